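"""Stepwise variable elimination scored by AICc.

Starting from the full variable set, each step screens against the
t-th highest contributing variable of the current model: every other
variable with percent contribution below 1% or with |Pearson r| above
0.7 against the screening variable is removed, the model is refitted,
and the step index (hence screening rank) advances. Each candidate is
scored with the small-sample Akaike information criterion computed
from the landscape-standardized raw likelihood, with the parameter
count k equal to the number of nonzero coefficients; the candidate
with the lowest valid AICc wins.

Categorical variables bypass the correlation screen and can only be
removed by the contribution rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import build_features
from .grids import RasterStack, extract_values
from .maxent import (
    MaxentModel,
    fit_maxent,
    landscape_table,
    merge_presences_into_background,
    sample_background,
    stack_table,
    variable_contribution,
)
from .occurrences import OccurrenceSet


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between continuous variables over a sample.

    Constant columns are excluded with a warning; fewer than 2 rows is an
    error. Diagonal is exactly 1.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    keep = []
    for c in table.columns:
        if np.asarray(table[c]).std() == 0:
            warnings.warn(f"constant column {c!r} excluded from correlation matrix")
        else:
            keep.append(c)
    corr = table[keep].corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _ranked(contributions: dict[str, float]) -> list[str]:
    """Variables by descending contribution, ties broken lexicographically."""
    return sorted(contributions, key=lambda v: (-contributions[v], v))


def reduction_step(
    contributions: dict[str, float],
    corr: pd.DataFrame,
    rank_t: int,
    r_cut: float = 0.7,
    c_cut: float = 1.0,
    var_kinds: dict | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """One screening pass against the rank_t-th highest contributor v*.

    Removes every variable other than v* whose contribution is below
    ``c_cut`` percent OR whose |r| with v* exceeds ``r_cut``; v* itself is
    never removed. Returns (retained variables, removed (name, reason)).
    """
    order = _ranked(contributions)
    if not (1 <= rank_t <= len(order)):
        raise ValueError(f"rank_t={rank_t} out of range for {len(order)} variables")
    var_kinds = var_kinds or {}
    vstar = order[rank_t - 1]
    retained, removed = [], []
    for v in order:
        if v == vstar:
            retained.append(v)
            continue
        if contributions[v] < c_cut:
            removed.append((v, "low_contribution"))
            continue
        categorical = var_kinds.get(v) == "categorical" or var_kinds.get(vstar) == "categorical"
        if not categorical and v in corr.index and vstar in corr.index:
            if abs(float(corr.loc[v, vstar])) > r_cut:
                removed.append((v, "high_correlation"))
                continue
        retained.append(v)
    return sorted(retained), removed


def compute_aicc(
    model: MaxentModel,
    pres_features: np.ndarray,
    landscape_features: np.ndarray,
) -> tuple[float, bool, int, float]:
    """AICc from the landscape-standardized raw likelihood.

    Raw output is renormalized to sum 1 over all unmasked study cells;
    lnL is the summed log probability at the presence cells; k counts the
    nonzero coefficients. Returns (aicc, valid, k, lnl); the score is
    invalid (excluded from winner choice) when k >= n - 1.
    """
    lam = model.lambdas
    pres_scores = np.asarray(pres_features, dtype=float) @ lam
    land_scores = np.asarray(landscape_features, dtype=float) @ lam
    lnZ_land = logsumexp(land_scores)
    lnl = float(np.sum(pres_scores - lnZ_land))
    k = model.k_nonzero
    n = model.n_presences
    if k >= n - 1:
        return float("nan"), False, k, lnl
    aicc = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
    return float(aicc), True, k, lnl


@dataclass
class CandidateModel:
    """One step of the elimination trace."""

    step: int
    variables: list[str]
    model: MaxentModel
    contributions: dict[str, float]
    aicc: float
    aicc_valid: bool
    k: int
    lnl: float
    removed: list[tuple[str, str]] = field(default_factory=list)  # removed to FORM this step


@dataclass
class SelectionTrace:
    candidates: list[CandidateModel]
    winner_index: int

    @property
    def winner(self) -> CandidateModel:
        return self.candidates[self.winner_index]

    def to_records(self) -> list[dict]:
        recs = []
        for c in self.candidates:
            recs.append(
                {
                    "step": c.step,
                    "n_variables": len(c.variables),
                    "variables": ";".join(c.variables),
                    "k_nonzero": c.k,
                    "lnL": c.lnl,
                    "AICc": c.aicc,
                    "aicc_valid": c.aicc_valid,
                    "winner": c.step - 1 == self.winner_index,
                    "removed": ";".join(f"{v}({r})" for v, r in c.removed),
                }
            )
        return recs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())

    def save_json(self, path) -> None:
        doc = {
            "winner_index": self.winner_index,
            "candidates": [
                {
                    "step": c.step,
                    "variables": c.variables,
                    "contributions": c.contributions,
                    "AICc": None if not c.aicc_valid else c.aicc,
                    "aicc_valid": c.aicc_valid,
                    "k_nonzero": c.k,
                    "lnL": c.lnl,
                    "removed": [list(t) for t in c.removed],
                }
                for c in self.candidates
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def select_variables(
    stack: RasterStack,
    occurrences: OccurrenceSet,
    background_n: int = 10000,
    seed: int = 0,
    reg_multiplier: float = 1.0,
    hinge_knots: int = 50,
    r_cut: float = 0.7,
    c_cut: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-5,
    presences_in_background: bool = True,
    rank_from: str = "current",
    background=None,
) -> SelectionTrace:
    """Run the full stepwise elimination and return the scored trace.

    One background sample (and one feature expansion) is shared by every
    candidate fit so AICc differences reflect the variable sets, not
    sampling noise. ``rank_from`` picks whether the step-t screening
    variable is ranked in the current model (default) or in the initial
    full model.
    """
    if rank_from not in ("current", "initial"):
        raise ValueError("rank_from must be 'current' or 'initial'")
    if len(stack.layers) < 2:
        raise ValueError("variable selection needs at least 2 variables")
    xy = occurrences.xy
    rows, cols = stack.spec.index_of(xy[:, 0], xy[:, 1])
    mask = stack.combined_mask()
    on_masked = mask[rows, cols]
    if on_masked.any():
        bad = [occurrences.ids[i] for i in np.nonzero(on_masked)[0]]
        raise ValueError(f"presences on masked cells: {', '.join(bad)}")

    bg = background if background is not None else sample_background(stack, n=background_n, seed=seed)
    if presences_in_background:
        bg = merge_presences_into_background(bg, rows, cols, stack)
    pres_table = stack_table(stack, rows, cols)
    land_table, _, _ = landscape_table(stack)

    var_kinds = {l.name: l.kind for l in stack.layers}
    n = len(occurrences)
    expansion = build_features(
        bg.table, var_kinds, n_presences=n, classes="auto", hinge_knots=hinge_knots
    )
    B_bg = expansion.transform(bg.table)
    B_pres = expansion.transform(pres_table)
    B_land = expansion.transform(land_table)
    continuous = [v for v in expansion.variables if var_kinds.get(v) != "categorical"]
    corr = pearson_matrix(bg.table[continuous]) if len(continuous) >= 2 else pd.DataFrame()

    fit_kwargs = dict(reg_multiplier=reg_multiplier, max_iter=max_iter, tol=tol)

    def fit_candidate(variables, step, removed, init=None):
        cols_ = expansion.columns_for(variables)
        model = fit_maxent(
            B_pres[:, cols_],
            B_bg[:, cols_],
            expansion=expansion.subset(variables),
            init=init,
            **fit_kwargs,
        )
        contrib = variable_contribution(model, B_pres[:, cols_], B_bg[:, cols_], **fit_kwargs)
        aicc, valid, k, lnl = compute_aicc(model, B_pres[:, cols_], B_land[:, cols_])
        return CandidateModel(step, sorted(variables), model, contrib, aicc, valid, k, lnl, removed)

    current = fit_candidate(expansion.variables, 1, [])
    candidates = [current]
    rank = 1
    while rank <= len(current.variables):
        source = current if rank_from == "current" else candidates[0]
        ranked_contrib = {v: source.contributions.get(v, 0.0) for v in current.variables}
        newvars, removed = reduction_step(
            ranked_contrib, corr, rank, r_cut=r_cut, c_cut=c_cut, var_kinds=var_kinds
        )
        if newvars != current.variables:
            cols_new = expansion.columns_for(newvars)
            # warm start from the current fit's coefficients on shared features
            pos = {j: i for i, j in enumerate(expansion.columns_for(current.variables))}
            init = np.array([current.model.lambdas[pos[j]] for j in cols_new])
            current = fit_candidate(newvars, len(candidates) + 1, removed, init=init)
            candidates.append(current)
        rank += 1

    valid = [i for i, c in enumerate(candidates) if c.aicc_valid]
    if not valid:
        raise ValueError(
            "no candidate has a valid AICc (k >= n-1 everywhere); "
            "use more presences or fewer features"
        )
    winner = min(valid, key=lambda i: (candidates[i].aicc, i))
    return SelectionTrace(candidates=candidates, winner_index=winner)
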