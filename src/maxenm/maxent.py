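"""L1-regularized maximum-entropy presence-only model.

The model is the Gibbs distribution over background cells
``p(x) = exp(sum_j lambda_j f_j(x)) / Z`` that maximizes the penalized
log-likelihood of the presence sample,

    J(lambda) = lambda . fbar_presence - ln Z(lambda) - sum_j beta_j |lambda_j|,

with per-feature penalty ``beta_j = r * s_j / sqrt(n)`` (r the
regularization multiplier, s_j the presence-sample standard deviation
of feature j floored at 1e-4, n the presence count). The regularized
training gain is ``J + ln m`` (improvement over the uniform
distribution on the m background cells, 0 at lambda = 0).

The objective is concave; it is maximized with L-BFGS-B on the
positive/negative split lambda = u - v (u, v >= 0), under which the L1
term is linear and the bound projection produces exact zeros.

Logistic output rescales the raw distribution so that a cell with
typical presence conditions scores 0.5:
``logistic = raw*e^H / (1 + raw*e^H)`` with H the entropy of the
fitted distribution over the background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureExpansion, build_features
from .grids import RasterStack


@dataclass
class BackgroundSample:
    """Background cells (the availability sample) and their raw values."""

    cell_rows: np.ndarray
    cell_cols: np.ndarray
    table: pd.DataFrame  # raw variable values, one row per cell

    @property
    def m(self) -> int:
        return len(self.table)


def stack_table(stack: RasterStack, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
    """Raw layer values at the given cells as a DataFrame (one column per layer)."""
    return pd.DataFrame(
        {l.name: np.ma.filled(l.values[rows, cols], np.nan) for l in stack.layers}
    )


def landscape_table(stack: RasterStack) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Raw values of every unmasked cell; returns (table, rows, cols)."""
    mask = stack.combined_mask()
    rows, cols = np.nonzero(~mask)
    return stack_table(stack, rows, cols), rows, cols


def sample_background(stack: RasterStack, n: int = 10000, seed: int = 0) -> BackgroundSample:
    """Draw up to n distinct unmasked cells uniformly without replacement."""
    mask = stack.combined_mask()
    rows, cols = np.nonzero(~mask)
    if len(rows) == 0:
        raise ValueError("stack has no unmasked cells")
    rng = np.random.default_rng(seed)
    take = min(n, len(rows))
    idx = rng.choice(len(rows), size=take, replace=False)
    idx.sort()
    rows, cols = rows[idx], cols[idx]
    return BackgroundSample(rows, cols, stack_table(stack, rows, cols))


def merge_presences_into_background(bg: BackgroundSample, pres_rows, pres_cols, stack) -> BackgroundSample:
    """Union of background and presence cells (standard normalization set)."""
    pres_rows = np.asarray(pres_rows)
    pres_cols = np.asarray(pres_cols)
    have = set(zip(bg.cell_rows.tolist(), bg.cell_cols.tolist()))
    keep = [i for i, rc in enumerate(zip(pres_rows.tolist(), pres_cols.tolist())) if rc not in have]
    if not keep:
        return bg
    rows = np.concatenate([bg.cell_rows, pres_rows[keep]])
    cols = np.concatenate([bg.cell_cols, pres_cols[keep]])
    return BackgroundSample(rows, cols, stack_table(stack, rows, cols))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy habitat suitability model."""

    expansion: FeatureExpansion
    lambdas: np.ndarray
    log_normalizer: float  # ln Z over the background sample
    entropy_H: float  # entropy of the fitted distribution over background
    reg_gain: float  # regularized training gain (>= 0 at the optimum)
    converged: bool
    iterations: int
    n_presences: int
    n_background: int
    reg_multiplier: float = 1.0
    beta: np.ndarray | None = None

    @property
    def k_nonzero(self) -> int:
        return int(np.count_nonzero(self.lambdas))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "maxenm-model-1",
            "expansion": self.expansion.to_dict(),
            "lambdas": self.lambdas.tolist(),
            "log_normalizer": self.log_normalizer,
            "entropy_H": self.entropy_H,
            "reg_gain": self.reg_gain,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_presences": self.n_presences,
            "n_background": self.n_background,
            "reg_multiplier": self.reg_multiplier,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, doc: dict) -> "MaxentModel":
        return cls(
            expansion=FeatureExpansion.from_dict(doc["expansion"]),
            lambdas=np.asarray(doc["lambdas"], dtype=float),
            log_normalizer=float(doc["log_normalizer"]),
            entropy_H=float(doc["entropy_H"]),
            reg_gain=float(doc["reg_gain"]),
            converged=bool(doc["converged"]),
            iterations=int(doc["iterations"]),
            n_presences=int(doc["n_presences"]),
            n_background=int(doc["n_background"]),
            reg_multiplier=float(doc.get("reg_multiplier", 1.0)),
        )

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _proximal_polish(
    lam: np.ndarray,
    B: np.ndarray,
    fbar: np.ndarray,
    beta: np.ndarray,
    max_iter: int = 200,
    rel_tol: float = 1e-10,
) -> tuple[np.ndarray, int]:
    """Proximal-gradient refinement of an L1 solution.

    The quasi-Newton solve leaves inactive coefficients loosely near
    zero; soft-thresholding steps drive them to exact zeros (the KKT
    condition |grad_j| <= beta_j holds at 0), which matters because the
    AICc parameter count is the number of nonzero coefficients.
    """

    def value(l):
        s = B @ l
        return logsumexp(s) - fbar @ l + beta @ np.abs(l)

    t = 1.0
    f_prev = value(lam)
    it = 0
    for it in range(1, max_iter + 1):
        s = B @ lam
        p = np.exp(s - logsumexp(s))
        g = p @ B - fbar
        while True:
            step = lam - t * g
            lam_new = np.sign(step) * np.maximum(np.abs(step) - t * beta, 0.0)
            f_new = value(lam_new)
            d = lam_new - lam
            # sufficient-decrease condition on the smooth part
            if f_new <= f_prev + g @ d + (d @ d) / (2 * t) + beta @ (np.abs(lam_new) - np.abs(lam)) + 1e-12:
                break
            t *= 0.5
            if t < 1e-12:
                lam_new, f_new = lam, f_prev
                break
        if abs(f_prev - f_new) <= rel_tol * max(abs(f_prev), 1.0):
            lam, f_prev = lam_new, f_new
            break
        lam, f_prev = lam_new, f_new
        t = min(t * 2.0, 1e6)
    return lam, it


def fit_maxent(
    pres_features: np.ndarray,
    bg_features: np.ndarray,
    expansion: FeatureExpansion | None = None,
    reg_multiplier: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-5,
    init: np.ndarray | None = None,
    polish: bool = True,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model on feature matrices.

    ``pres_features`` (n, F) and ``bg_features`` (m, F) must come from the
    same expansion (features in [0, 1]). Stops when the relative objective
    change drops below ``tol`` or after ``max_iter`` iterations; a model
    that hits the cap is returned with ``converged=False`` and a warning.
    """
    P = np.asarray(pres_features, dtype=float)
    B = np.asarray(bg_features, dtype=float)
    if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
        raise ValueError("presence/background feature matrices are inconsistent")
    n, F = P.shape
    m = B.shape[0]
    if n < 1 or m < 2:
        raise ValueError("need at least 1 presence and 2 background points")
    fbar = P.mean(axis=0)
    s = P.std(axis=0)
    beta = reg_multiplier * np.maximum(s, 1e-4) / np.sqrt(n)

    def objective(w):
        lam = w[:F] - w[F:]
        scores = B @ lam
        lnZ = logsumexp(scores)
        p = np.exp(scores - lnZ)
        Ef = p @ B
        f = lnZ - fbar @ lam + beta @ (w[:F] + w[F:])
        g = Ef - fbar
        grad = np.concatenate([g + beta, -g + beta])
        return f, grad

    if init is not None:
        lam0 = np.asarray(init, dtype=float)
        w0 = np.concatenate([np.maximum(lam0, 0.0), np.maximum(-lam0, 0.0)])
    else:
        w0 = np.zeros(2 * F)
    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * F),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9, "maxcor": 20},
    )
    converged = bool(res.status == 0)
    if not converged:
        warnings.warn(f"maxent fit hit the {max_iter}-iteration cap without converging")
    lam = res.x[:F] - res.x[F:]
    polish_iters = 0
    if polish:
        lam, polish_iters = _proximal_polish(lam, B, fbar, beta)
    scores = B @ lam
    lnZ = float(logsumexp(scores))
    p = np.exp(scores - lnZ)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    reg_gain = float(fbar @ lam - lnZ - beta @ np.abs(lam) + np.log(m))
    return MaxentModel(
        expansion=expansion,
        lambdas=lam,
        log_normalizer=lnZ,
        entropy_H=H,
        reg_gain=reg_gain,
        converged=converged,
        iterations=int(res.nit) + polish_iters,
        n_presences=n,
        n_background=m,
        reg_multiplier=reg_multiplier,
        beta=beta,
    )


def predict(model: MaxentModel, features: np.ndarray, output: str = "logistic") -> np.ndarray:
    """Suitability of feature rows; ``raw`` sums to 1 over the background."""
    scores = np.asarray(features, dtype=float) @ model.lambdas
    log_raw = scores - model.log_normalizer
    if output == "raw":
        return np.exp(log_raw)
    if output == "logistic":
        # numerically stable raw*e^H / (1 + raw*e^H)
        t = log_raw + model.entropy_H
        out = np.empty_like(t)
        pos = t >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
        out[~pos] = np.exp(t[~pos]) / (1.0 + np.exp(t[~pos]))
        return out
    raise ValueError(f"unknown output type {output!r}")


def predict_table(model: MaxentModel, table, output: str = "logistic") -> np.ndarray:
    """Predict from a raw variable-value table via the model's expansion."""
    return predict(model, model.expansion.transform(table), output=output)


# ---------------------------------------------------------------------------
# Variable-level diagnostics


def variable_contribution(
    model: MaxentModel,
    pres_features: np.ndarray,
    bg_features: np.ndarray,
    **fit_kwargs,
) -> dict[str, float]:
    """Percent contribution per variable via leave-one-variable-out gain drops.

    drop_v = max(0, gain(full) - gain(refit without v's features));
    contributions are the drops normalized to sum 100. A single-variable
    model reports 100 by convention. If every drop is zero the
    contributions are returned all-zero.
    """
    exp = model.expansion
    variables = exp.variables
    if not variables:
        raise ValueError("model has no variables")
    if len(variables) == 1:
        return {variables[0]: 100.0}
    fit_kwargs.setdefault("reg_multiplier", model.reg_multiplier)
    fit_kwargs.setdefault("polish", False)  # drops use the gain only, not the support
    drops = {}
    for v in variables:
        rest = [u for u in variables if u != v]
        cols = exp.columns_for(rest)
        sub = fit_maxent(
            pres_features[:, cols],
            bg_features[:, cols],
            expansion=exp.subset(rest),
            init=model.lambdas[cols],
            **fit_kwargs,
        )
        drops[v] = max(0.0, model.reg_gain - sub.reg_gain)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in variables}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_auc(
    pres_features: np.ndarray,
    bg_features: np.ndarray,
    expansion: FeatureExpansion,
    **fit_kwargs,
) -> dict[str, float]:
    """AUC (presences vs background) of single-variable models, per variable."""
    from .evaluation import rank_auc

    variables = expansion.variables
    if len(variables) < 2:
        raise ValueError("jackknife requires at least 2 variables")
    fit_kwargs.setdefault("polish", False)  # single-variable AUC does not use the support
    out = {}
    for v in variables:
        cols = expansion.columns_for([v])
        if len(cols) == 0:
            warnings.warn(f"variable {v!r} has no usable features; AUC 0.5 reported")
            out[v] = 0.5
            continue
        sub = fit_maxent(
            pres_features[:, cols], bg_features[:, cols], expansion=expansion.subset([v]), **fit_kwargs
        )
        if sub.k_nonzero == 0:
            warnings.warn(f"variable {v!r} fit is degenerate; AUC 0.5 reported")
            out[v] = 0.5
            continue
        pos = predict(sub, pres_features[:, cols], output="raw")
        neg = predict(sub, bg_features[:, cols], output="raw")
        out[v] = rank_auc(pos, neg)
    return out


@dataclass
class ResponseCurve:
    """Suitability response to one variable, others held at background means."""

    variable: str
    grid: np.ndarray  # variable values swept
    mean: np.ndarray  # mean logistic suitability across models
    sd: np.ndarray  # spread across models (0 for a single model)

    @property
    def peak(self) -> float:
        """Variable value at the maximum of the mean response."""
        return float(self.grid[int(np.argmax(self.mean))])


def response_curve(models, variable: str, n_points: int = 100) -> ResponseCurve:
    """Sweep one variable over its background range, others at background
    means (categorical variables at their modal code)."""
    if isinstance(models, MaxentModel):
        models = [models]
    exp = models[0].expansion
    if variable not in exp.variables:
        raise KeyError(f"variable {variable!r} not in model")
    if exp.var_kinds.get(variable) == "categorical":
        grid = np.array(sorted({d.code for d in exp.defs if d.var == variable and d.code is not None}), dtype=float)
    else:
        lo, hi = exp.scaling[variable]
        grid = np.linspace(lo, hi, n_points)
    table = {}
    for v in exp.variables:
        if v == variable:
            table[v] = grid
        elif exp.var_kinds.get(v) == "categorical":
            table[v] = np.full(len(grid), exp.bg_mode[v], dtype=float)
        else:
            table[v] = np.full(len(grid), exp.bg_mean[v])
    preds = np.vstack([predict_table(mdl, table, output="logistic") for mdl in models])
    return ResponseCurve(variable=variable, grid=grid, mean=preds.mean(axis=0), sd=preds.std(axis=0))
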