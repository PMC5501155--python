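"""Model evaluation: pseudo-absences, AUC, maximized Kappa / TSS, and
the replicate bootstrap harness.

AUC uses the rank (Mann-Whitney) formulation against background
points; the threshold-dependent Kappa and TSS are maximized over a
0.001-step threshold grid against a fixed set of pseudo-absence points
drawn outside exclusion buffers around the presences. "Bootstrap"
replicates are repeated random 75/25 train/test splits of the presence
set (without replacement); a resample-with-replacement mode is also
available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .grids import RasterStack
from .maxent import (
    BackgroundSample,
    fit_maxent,
    predict,
    stack_table,
)
from .occurrences import OccurrenceSet


# ---------------------------------------------------------------------------
# Pseudo-absences


def generate_pseudo_absences(
    stack: RasterStack,
    presences: OccurrenceSet,
    n: int = 200,
    exclusion_radius: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """n pseudo-absence points (cell centers) uniform over unmasked cells
    at least ``exclusion_radius`` from every presence. Returns (n, 2) xy."""
    mask = stack.combined_mask()
    rows, cols = np.nonzero(~mask)
    spec = stack.spec
    cx = spec.origin_x + (cols + 0.5) * spec.cell_size
    cy = spec.origin_y - (rows + 0.5) * spec.cell_size
    eligible = np.ones(len(rows), dtype=bool)
    if len(presences) > 0:
        tree = cKDTree(presences.xy)
        d, _ = tree.query(np.column_stack([cx, cy]), k=1)
        eligible = d >= exclusion_radius
    idx = np.nonzero(eligible)[0]
    if len(idx) == 0:
        raise ValueError("no unmasked cells outside the exclusion buffers")
    if len(idx) < n:
        raise ValueError(
            f"only {len(idx)} eligible cells for {n} pseudo-absences; reduce n"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(idx, size=n, replace=False)
    take.sort()
    return np.column_stack([cx[take], cy[take]])


# ---------------------------------------------------------------------------
# Threshold-independent and threshold-dependent statistics


def rank_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) with ties counted half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank_auc needs at least one score on each side")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, TSS = sens + spec - 1, and Cohen's kappa."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both observed classes must be non-empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    n = tp + fn + tn + fp
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1 - pe)
    return {"sensitivity": sens, "specificity": spec, "tss": sens + spec - 1, "kappa": kappa}


def maximize_threshold(
    pos_scores, neg_scores, metric: str = "tss", step: float = 0.001
) -> tuple[float, float]:
    """Scan thresholds 0, step, ..., 1 (score >= threshold => presence) and
    return (smallest maximizing threshold, maximum metric value)."""
    if metric not in ("tss", "kappa"):
        raise ValueError("metric must be 'tss' or 'kappa'")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    # vectorized confusion counts over the whole grid
    tp = (pos[None, :] >= thresholds[:, None]).sum(axis=1)
    fp = (neg[None, :] >= thresholds[:, None]).sum(axis=1)
    fn = pos.size - tp
    tn = neg.size - fp
    sens = tp / pos.size
    spc = tn / neg.size
    if metric == "tss":
        values = sens + spc - 1
    else:
        n = pos.size + neg.size
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(pe == 1.0, 0.0, (po - pe) / (1 - pe))
    best = int(np.argmax(values))  # argmax returns the first (smallest) maximizer
    return float(thresholds[best]), float(values[best])


_AUC_BINS = [(0.9, "excellent"), (0.8, "good"), (0.7, "fair"), (0.6, "poor"), (0.5, "failed")]
_KAPPA_BINS = [(0.75, "excellent"), (0.4, "good"), (None, "poor")]
_TSS_BINS = [(0.8, "good to excellent"), (0.5, "useful"), (0.2, "poor")]


def performance_class(statistic: str, value: float) -> str:
    """Qualitative performance label for AUC / Kappa / TSS values.

    Boundary values are assigned to the higher class.
    """
    if statistic == "auc":
        if not 0.0 <= value <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        for cut, label in _AUC_BINS:
            if value >= cut:
                return label
        return "failed"
    if statistic == "kappa":
        if not -1.0 <= value <= 1.0:
            raise ValueError("Kappa must lie in [-1, 1]")
        for cut, label in _KAPPA_BINS:
            if cut is None or value >= cut:
                return label
    if statistic == "tss":
        if not -1.0 <= value <= 1.0:
            raise ValueError("TSS must lie in [-1, 1]")
        for cut, label in _TSS_BINS:
            if value >= cut:
                return label
        return "no better than random"
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Replicate harness


@dataclass
class ReplicateResult:
    index: int
    train_ids: list[str]
    test_ids: list[str]
    training_auc: float
    test_auc: float
    max_kappa: float
    kappa_threshold: float
    max_tss: float
    tss_threshold: float
    prediction: np.ndarray  # logistic suitability grid (masked array)
    model: object = None


@dataclass
class EvaluationSummary:
    replicates: list[ReplicateResult]
    mean_training_auc: float
    mean_test_auc: float
    mean_max_kappa: float
    mean_max_tss: float
    mean_tss_threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "replicate": r.index,
                "n_train": len(r.train_ids),
                "n_test": len(r.test_ids),
                "training_auc": r.training_auc,
                "test_auc": r.test_auc,
                "max_kappa": r.max_kappa,
                "kappa_threshold": r.kappa_threshold,
                "max_tss": r.max_tss,
                "tss_threshold": r.tss_threshold,
            }
            for r in self.replicates
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_replicates": len(self.replicates),
            "mean_training_auc": self.mean_training_auc,
            "mean_test_auc": self.mean_test_auc,
            "mean_max_kappa": self.mean_max_kappa,
            "mean_max_tss": self.mean_max_tss,
            "mean_tss_threshold": self.mean_tss_threshold,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def bootstrap_evaluate(
    stack: RasterStack,
    variables: list[str],
    presences: OccurrenceSet,
    pseudo_absences: np.ndarray,
    background: BackgroundSample,
    expansion,
    reps: int = 20,
    train_frac: float = 0.75,
    seed: int = 0,
    threshold_step: float = 0.001,
    replicate_mode: str = "split",
    keep_models: bool = False,
    **fit_kwargs,
) -> EvaluationSummary:
    """Replicate evaluation of the final variable set.

    Per replicate: a random train/test presence split (train count =
    round(train_frac * n)), a fit on the training presences against the
    shared background, training and test AUC against background scores,
    maximized Kappa and TSS of the test presences against the (fixed)
    pseudo-absence scores, and the full logistic prediction grid.
    ``replicate_mode='resample'`` draws the training set with replacement
    instead of splitting.
    """
    if replicate_mode not in ("split", "resample"):
        raise ValueError("replicate_mode must be 'split' or 'resample'")
    n = len(presences)
    if n < 4:
        raise ValueError("need at least 4 presences for train/test replication")
    n_train = int(round(train_frac * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError("train fraction leaves an empty train or test set")

    spec = stack.spec
    xy = presences.xy
    prow, pcol = spec.index_of(xy[:, 0], xy[:, 1])
    pres_table = stack_table(stack, prow, pcol)
    exp_sub = expansion.subset(variables)
    B_pres = exp_sub.transform(pres_table)
    B_bg = exp_sub.transform(background.table)
    arow, acol = spec.index_of(pseudo_absences[:, 0], pseudo_absences[:, 1])
    B_abs = exp_sub.transform(stack_table(stack, arow, acol))
    mask = stack.combined_mask()
    lrow, lcol = np.nonzero(~mask)
    B_land = exp_sub.transform(stack_table(stack, lrow, lcol))

    rng = np.random.default_rng(seed)
    results: list[ReplicateResult] = []
    ids = np.asarray(presences.ids)
    for rep in range(reps):
        if replicate_mode == "split":
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
        else:
            train_idx = rng.integers(0, n, size=n_train)
            test_idx = np.setdiff1d(np.arange(n), np.unique(train_idx))
            if len(test_idx) == 0:
                raise ValueError("resample replicate left no test presences")
        model = fit_maxent(B_pres[train_idx], B_bg, expansion=exp_sub, **fit_kwargs)
        bg_scores = predict(model, B_bg, output="logistic")
        train_scores = predict(model, B_pres[train_idx], output="logistic")
        test_scores = predict(model, B_pres[test_idx], output="logistic")
        abs_scores = predict(model, B_abs, output="logistic")
        thr_k, max_k = maximize_threshold(test_scores, abs_scores, "kappa", threshold_step)
        thr_t, max_t = maximize_threshold(test_scores, abs_scores, "tss", threshold_step)
        grid = np.ma.masked_all((spec.n_rows, spec.n_cols))
        grid[lrow, lcol] = predict(model, B_land, output="logistic")
        results.append(
            ReplicateResult(
                index=rep,
                train_ids=ids[train_idx].tolist(),
                test_ids=ids[test_idx].tolist(),
                training_auc=rank_auc(train_scores, bg_scores),
                test_auc=rank_auc(test_scores, bg_scores),
                max_kappa=max_k,
                kappa_threshold=thr_k,
                max_tss=max_t,
                tss_threshold=thr_t,
                prediction=grid,
                model=model if keep_models else None,
            )
        )
    return EvaluationSummary(
        replicates=results,
        mean_training_auc=float(np.mean([r.training_auc for r in results])),
        mean_test_auc=float(np.mean([r.test_auc for r in results])),
        mean_max_kappa=float(np.mean([r.max_kappa for r in results])),
        mean_max_tss=float(np.mean([r.max_tss for r in results])),
        mean_tss_threshold=float(np.mean([r.tss_threshold for r in results])),
    )
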