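"""MaxEnt-style feature expansion of environmental variables.

Continuous variables are rescaled to [0, 1] using their background
min/max (values outside the training range are clamped) and expanded
into linear, quadratic, hinge (forward and reverse, sharing the hinge
budget) and pairwise-product features;
categorical variables expand into per-category indicators. Every
feature maps any input to [0, 1].

Which classes are used follows the sample-size auto rule:
fewer than 10 presences -> linear only; 10-14 -> + quadratic;
15-79 -> + hinge; 80 or more -> + product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("linear", "quadratic", "hinge", "product", "indicator")
_HINGE_TYPES = ("hinge", "rhinge")  # forward and reverse hinges share the class budget


def auto_feature_classes(n_presences: int) -> set[str]:
    """Feature classes enabled for a given presence count."""
    classes = {"linear"}
    if n_presences >= 10:
        classes.add("quadratic")
    if n_presences >= 15:
        classes.add("hinge")
    if n_presences >= 80:
        classes.add("product")
    return classes


@dataclass(frozen=True)
class FeatureDef:
    """One derived feature: class, source variable(s) and parameters."""

    ftype: str  # linear | quadratic | hinge | product | indicator
    var: str
    var2: str | None = None  # product partner
    knot: float | None = None  # hinge knot, in rescaled [0,1] units
    code: int | None = None  # category code

    @property
    def variables(self) -> frozenset:
        return frozenset((self.var, self.var2)) if self.var2 else frozenset((self.var,))

    @property
    def name(self) -> str:
        if self.ftype == "linear":
            return self.var
        if self.ftype == "quadratic":
            return f"{self.var}^2"
        if self.ftype == "product":
            return f"{self.var}*{self.var2}"
        if self.ftype == "hinge":
            return f"hinge({self.var},{self.knot:.6g})"
        if self.ftype == "rhinge":
            return f"rhinge({self.var},{self.knot:.6g})"
        return f"{self.var}=={self.code}"


@dataclass
class FeatureExpansion:
    """Frozen mapping from raw variable tables to the [0,1] feature matrix."""

    defs: list[FeatureDef]
    scaling: dict  # var -> (min, max) over background, continuous only
    var_kinds: dict  # var -> "continuous" | "categorical"
    bg_mean: dict = field(default_factory=dict)  # var -> background mean (continuous)
    bg_mode: dict = field(default_factory=dict)  # var -> modal code (categorical)

    @property
    def n_features(self) -> int:
        return len(self.defs)

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.defs]

    @property
    def variables(self) -> list[str]:
        out: list[str] = []
        for d in self.defs:
            for v in sorted(d.variables):
                if v not in out:
                    out.append(v)
        return sorted(out)

    def _rescaled(self, table, var: str) -> np.ndarray:
        lo, hi = self.scaling[var]
        x = np.asarray(table[var], dtype=float)
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def transform(self, table) -> np.ndarray:
        """Feature matrix (n, n_features) for a table of raw variable values.

        ``table`` is anything indexable by variable name (DataFrame or dict
        of arrays). Values outside the background range are clamped.
        """
        n = len(np.asarray(table[self.defs[0].var])) if self.defs else 0
        out = np.empty((n, len(self.defs)), dtype=float)
        cache: dict[str, np.ndarray] = {}

        def z(var: str) -> np.ndarray:
            if var not in cache:
                cache[var] = self._rescaled(table, var)
            return cache[var]

        for j, d in enumerate(self.defs):
            if d.ftype == "linear":
                out[:, j] = z(d.var)
            elif d.ftype == "quadratic":
                out[:, j] = z(d.var) ** 2
            elif d.ftype == "product":
                out[:, j] = z(d.var) * z(d.var2)
            elif d.ftype == "hinge":
                out[:, j] = np.clip((z(d.var) - d.knot) / (1.0 - d.knot), 0.0, 1.0)
            elif d.ftype == "rhinge":
                out[:, j] = np.clip((d.knot - z(d.var)) / d.knot, 0.0, 1.0)
            elif d.ftype == "indicator":
                out[:, j] = (np.asarray(table[d.var]) == d.code).astype(float)
            else:  # pragma: no cover
                raise ValueError(d.ftype)
        return out

    def columns_for(self, variables) -> np.ndarray:
        """Indices of features whose source variables all lie in ``variables``."""
        vs = set(variables)
        return np.array([j for j, d in enumerate(self.defs) if d.variables <= vs], dtype=int)

    def subset(self, variables) -> "FeatureExpansion":
        """Expansion restricted to the given variables (scaling preserved)."""
        cols = self.columns_for(variables)
        return FeatureExpansion(
            defs=[self.defs[j] for j in cols],
            scaling=dict(self.scaling),
            var_kinds=dict(self.var_kinds),
            bg_mean=dict(self.bg_mean),
            bg_mode=dict(self.bg_mode),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "defs": [
                {k: v for k, v in d.__dict__.items() if v is not None} for d in self.defs
            ],
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "var_kinds": dict(self.var_kinds),
            "bg_mean": dict(self.bg_mean),
            "bg_mode": {k: int(v) for k, v in self.bg_mode.items()},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureExpansion":
        return cls(
            defs=[FeatureDef(**d) for d in doc["defs"]],
            scaling={k: tuple(v) for k, v in doc["scaling"].items()},
            var_kinds=dict(doc["var_kinds"]),
            bg_mean=dict(doc.get("bg_mean", {})),
            bg_mode={k: int(v) for k, v in doc.get("bg_mode", {}).items()},
        )


def build_features(
    background,
    var_kinds: dict | None = None,
    n_presences: int = 15,
    classes="auto",
    hinge_knots: int = 50,
) -> FeatureExpansion:
    """Build a feature expansion from a background value table.

    ``background``: DataFrame (or dict of arrays) of raw variable values
    over the background sample; scaling, hinge knots and reference
    means/modes all come from it. ``classes`` is "auto" (sample-size
    rule on ``n_presences``) or an explicit set of class names.
    Constant variables contribute no features (warning).
    """
    if isinstance(background, pd.DataFrame):
        variables = list(background.columns)
    else:
        variables = list(background.keys())
    if not variables or len(np.asarray(background[variables[0]])) == 0:
        raise ValueError("background table is empty")
    if var_kinds is None:
        var_kinds = {v: "continuous" for v in variables}
    if classes == "auto":
        classes = auto_feature_classes(n_presences)
    else:
        classes = set(classes)
        unknown = classes - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")

    defs: list[FeatureDef] = []
    scaling: dict = {}
    bg_mean: dict = {}
    bg_mode: dict = {}
    continuous: list[str] = []

    for v in variables:
        x = np.asarray(background[v], dtype=float)
        x = x[np.isfinite(x)]
        if var_kinds.get(v, "continuous") == "categorical":
            codes, counts = np.unique(x.astype(int), return_counts=True)
            if len(codes) < 2:
                warnings.warn(f"categorical variable {v!r} is constant over background; dropped")
                continue
            bg_mode[v] = int(codes[np.argmax(counts)])
            for code in codes:
                defs.append(FeatureDef("indicator", v, code=int(code)))
            continue
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            warnings.warn(f"variable {v!r} is constant over background; dropped")
            continue
        scaling[v] = (lo, hi)
        bg_mean[v] = float(x.mean())
        continuous.append(v)
        defs.append(FeatureDef("linear", v))
        if "quadratic" in classes:
            defs.append(FeatureDef("quadratic", v))
        if "hinge" in classes:
            z = (x - lo) / (hi - lo)
            # hinge budget split between forward and reverse hinges so both
            # flanks of a response can bend sharply
            n_fwd = (hinge_knots + 1) // 2
            n_rev = hinge_knots // 2
            fwd = np.quantile(z, np.arange(n_fwd) / n_fwd)
            for t in fwd[fwd < 1.0]:
                defs.append(FeatureDef("hinge", v, knot=float(t)))
            rev = np.quantile(z, (np.arange(n_rev) + 1) / n_rev)
            for t in rev[rev > 0.0]:
                defs.append(FeatureDef("rhinge", v, knot=float(t)))
    if "product" in classes:
        for i, a in enumerate(continuous):
            for b in continuous[i + 1 :]:
                defs.append(FeatureDef("product", a, var2=b))
    return FeatureExpansion(
        defs=defs, scaling=scaling, var_kinds=dict(var_kinds), bg_mean=bg_mean, bg_mode=bg_mode
    )
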