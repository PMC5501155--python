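# Methods

## The estimation problem

Presence-only habitat modeling infers a suitability surface from
occurrence locations plus a background sample describing available
conditions, without confirmed absences. `maxenm` implements the
maximum-entropy formulation: among all distributions over background
cells whose feature expectations match the presence sample, take the
one of maximum entropy — equivalently, the Gibbs distribution
`p(x) ∝ exp(Σ λ_j f_j(x))` maximizing the L1-penalized presence
log-likelihood. The L1 penalty `β_j = r·s_j/√n` scales each feature's
penalty by its presence-sample standard deviation and shrinks with the
presence count, so small samples get simpler models. This per-feature
rule is a deliberate simplification of the per-feature-class
interpolation tables used by the original MaxEnt program; it preserves
the scale behavior (β ∝ s/√n) with one interpretable multiplier `r`
(default 1).

### Features

Continuous variables are min/max rescaled to [0, 1] over the background
(values beyond the training range are clamped, so predictions never
extrapolate) and expanded into linear, quadratic, hinge and pairwise
product features; categorical variables become one indicator per
observed code. Which classes are active follows the presence-count auto
rule (linear below 10; + quadratic from 10; + hinge from 15; + product
from 80). The hinge budget (`hinge_knots`, default 50 per variable) is
split between forward hinges `max(0, z−t)/(1−t)` and reverse hinges
`max(0, t−z)/t` with knots at evenly spaced background quantiles.
Forward-only hinges can bend a response sharply only on its upper
flank, which visibly skews fitted optima of narrow unimodal responses;
the two-sided split removes that asymmetry at the same feature count.

### Solver

The objective is concave. It is maximized by L-BFGS-B on the
positive/negative split `λ = u − v, u,v ≥ 0` (the L1 term becomes
linear; convergence when the relative objective change drops below
`tol`, default 1e-5, cap 500 iterations), followed by a
proximal-gradient polish (soft-thresholding with backtracking line
search, up to 200 steps). The polish matters because the quasi-Newton
solution leaves inactive coefficients loosely near zero, while the AICc
parameter count is defined as the number of *exactly* nonzero
coefficients; soft-thresholding satisfies the zero-coefficient KKT
condition `|∂_j lnZ − f̄_j| ≤ β_j` exactly. Refits used only for gain
comparisons (percent contribution, single-variable AUC) skip the polish.
Degenerate inputs: constant features are dropped at expansion time with
a warning; a fit hitting the iteration cap is returned flagged
`converged=False`.

### Outputs

Raw output is the fitted probability mass over the background (sums
to 1). The logistic index `p·e^H/(1+p·e^H)` (H = entropy of the fitted
distribution) maps a cell with typical presence conditions to 0.5 and
is the surface used for mapping. Percent contribution is computed by
deterministic leave-one-variable-out refits — `drop_v = max(0,
gain(full) − gain(without v))`, normalized to 100% — rather than the
original optimizer-path attribution, trading exact MaxEnt-output
compatibility for reproducibility across solvers. The variable
jackknife fits each variable alone and reports presence-vs-background
AUC. Response curves sweep one variable over its background range with
the others fixed at background means (categorical at mode).

## Occurrence thinning

Records whose home-range buffers overlap are collapsed to one per
connected overlap component (single-linkage on "center distance
< 2·radius"), one representative chosen uniformly at random. Connected
components make the retained *count* independent of the seed; only the
representatives vary. The default radius 564.19 m is the circle of
exactly 1 km² area — the analysis regards the stated "1 km² buffer" as
circular; both this and the 1 km pseudo-absence exclusion radius are
config-exposed because the two conventions (area-based vs
distance-based) differ by ~2x in radius. Buffers that merely touch
(distance exactly 2r) do not overlap.

## Variable selection

Step 1 fits all variables. Step t ranks the current model's
contributions (ties broken by name) and screens against the t-th
highest contributor v*: every other variable with contribution < 1% or
|Pearson r| > 0.7 with v* is removed, the model refit, and the rank
advanced; the loop ends when the rank exceeds the remaining variable
count. The screening rank is taken from the *current* model
(`rank_from="current"`); ranking in the initial model is available as a
config option since the narrative phrase "second highest contributed
variable" is ambiguous between the two. Correlations are computed on
the background sample (config-exposed); categorical variables bypass
the correlation screen. One background sample and one feature expansion
are shared by all candidate fits so AICc differences reflect variable
sets, not sampling noise.

AICc uses the landscape-standardized likelihood: raw output is
renormalized to sum 1 over every unmasked study cell, `lnL` is the sum
of log-probabilities at presence cells, `k` the nonzero-coefficient
count, and `AICc = 2k − 2lnL + 2k(k+1)/(n−k−1)`, invalid (excluded from
the winner choice) when `k ≥ n−1`.

## Evaluation

"Bootstrap" replicates are repeated random 75/25 train/test splits
without replacement (train count = round(0.75·n)); a true
resample-with-replacement mode exists behind `replicate_mode`. AUC is
the rank (Mann–Whitney) statistic of presences against *background*
scores — the convention built into presence-only software — while the
threshold-dependent Kappa and TSS are computed for test presences
against 200 fixed pseudo-absence points drawn uniformly outside 1 km
exclusion buffers (generated once, reused across replicates). Threshold
maximization scans 0 to 1 in steps of 0.001, scores ≥ threshold count
as predicted presence, and the smallest maximizer is reported
(deterministic tie-break). Performance labels follow the conventional
bins (AUC: excellent > 0.9, good > 0.8, fair > 0.7, poor > 0.6, else
failed; Kappa: excellent > 0.75, good > 0.4, else poor; TSS: good to
excellent > 0.8, useful > 0.5, poor > 0.2), with boundary values
assigned upward.

## Habitat accounting

The final suitability map is the cell-wise mean of the replicate
logistic grids; the binary map applies the mean max-TSS threshold with
`value ≥ threshold` suitable. Areas are suitable-cell counts times the
cell area. Zones use the center-point rule (a cell belongs to a zone iff
its center is inside the polygon) — deterministic and
resolution-limited, so zone areas can differ from exact polygon-clipped
GIS figures by boundary cells; the protected fraction uses the
cell-wise union of reserves so overlapping reserves are not
double-counted. Proportions are printed at 2 decimals, half-up. Patches
are connected components at 8-connectivity by default (diagonal
ridgelines connect).

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

- **Fields.** Gaussian-kernel-smoothed white noise (wrap-around
  boundary), standardized to mean 0 / variance 1; default length scale
  2,500 m (10 cells) gives the large, smooth patches of interpolated
  climate surfaces.
- **Truth.** Suitability is the *product* of per-variable response
  factors — unimodal Gaussian `exp(−(v−μ)²/2σ²)`, increasing-saturating
  `min(1, v/d₀)`, or flat — multiplicative because independent
  limiting factors yield the unimodal marginal response shapes real
  fitted curves show (an additive mixture would not).
- **Default conditions.** 200×200 cells of 250 m; two informative
  variables with optima μ = ±0.5 and breadth σ = 0.25 (standardized
  field units); one duplicate of the first at Pearson r = 0.9; three
  noise fields; 150 presences. σ = 0.25 is chosen so the truth itself
  is strongly structured: scoring cells by the true suitability
  separates presences from background at AUC ≈ 0.95, and ~90% of
  presence mass lies in the top tenth of the landscape — the
  narrow-niche, highly localized regime this workflow targets. Wider
  niches (σ ≥ 0.5) put the *ideal* model's AUC below 0.85, so no
  fitted model could look strongly discriminating.
- **Duplicates.** `dup = r·v + √(1−r²)·ε⊥` with the helper field
  orthogonalized against the source over the grid, so the realized
  full-grid correlation equals the target exactly (background-sample
  correlation then deviates by sampling only, well within ±0.03).
- **Presences.** Cells drawn without replacement with probability
  proportional to the truth (Gumbel-key weighted sampling), placed at
  cell centers — one record per cell, mirroring the post-thinning
  structure of real data.

What passing recovery tests do *not* show about real data: the
generator has no sampling bias toward roads or accessibility, no
observation error in coordinates, no categorical land-cover layer in
the default set, and its fields are stationary and Gaussian — real
environmental layers are none of these. Recovery results bound what
the pipeline can do when its assumptions hold, not field performance.

## Problem sizes and determinism

The recovery study in `scripts/acceptance.py` uses 20 landscapes for
the selection-recovery rate, 10 (at 200 presences, per the
response-curve recovery convention) for optimum-recovery error, and 3
landscapes × 20 replicates for the evaluation statistics — sizes at
which the binomial uncertainty on the reported rates is a few percent
while a full run stays around two minutes on one core. Every random
stage takes a seed; the pipeline derives one seed per stage as a hash
of the master seed and the stage name, and the whole synthetic
generation is a pure function of its config, so reruns are
byte-identical. The default master seed (20170705) is an arbitrary
date-style constant.

## Known limitations

- No reprojection or resampling: all rasters must already share one
  grid (misalignment beyond 1e-6 relative tolerance is an error).
- No threshold features, cloglog output, or extrapolation diagnostics
  (MESS); clamping is the only out-of-range behavior.
- AICc's `k` depends on exact coefficient sparsity and hence mildly on
  solver tolerances; the polish step makes it stable but it is not a
  model-free quantity.
- Zonal areas are center-point approximations, not polygon-clipped.
- The percent-contribution convention differs from the original MaxEnt
  program's path-dependent attribution (deterministic by design);
  contribution values are comparable within this package, not with
  MaxEnt output files.
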