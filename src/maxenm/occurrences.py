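"""Georeferenced presence records and spatial thinning.

Presence-only records cluster around survey effort; to limit spatial
autocorrelation and model overfitting, records whose home-range buffers
overlap are thinned to a single representative per overlapping group.
The default buffer is a circle of 1 km^2 area (radius 564.19 m),
approximating the species' minimum home range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: radius (m) of a circle of exactly 1 km^2 area
ONE_KM2_RADIUS = float(np.sqrt(1e6 / np.pi))  # 564.1896 m


@dataclass(frozen=True)
class OccurrenceRecord:
    id: str
    x: float
    y: float
    source: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"record {self.id!r} has non-finite coordinates")


@dataclass
class OccurrenceSet:
    """A collection of presence records, optionally spatially thinned."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    thinned: bool = False
    thin_radius: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(-1, 2)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "source": [r.source for r in self.records],
                "year": [r.year for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, thinned: bool = False, thin_radius=None) -> "OccurrenceSet":
        records = [
            OccurrenceRecord(
                id=str(row["id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                source=str(row.get("source", "")),
                year=int(row["year"]) if "year" in df.columns and pd.notna(row["year"]) else None,
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, thinned=thinned, thin_radius=thin_radius)


def read_occurrences(path) -> OccurrenceSet:
    """Read a presence CSV with header ``id,x,y,source,year`` (x/y in meters)."""
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing occurrence columns {sorted(missing)}")
    return OccurrenceSet.from_frame(df)


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.to_frame().to_csv(path, index=False)


def _connected_components(n: int, pairs) -> list[list[int]]:
    """Union-find over overlap pairs; components returned sorted by least member."""
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[k] for k in sorted(groups)]


def thin_occurrences(occ: OccurrenceSet, buffer_radius: float = ONE_KM2_RADIUS, seed: int = 0) -> OccurrenceSet:
    """Thin records whose circular buffers overlap to one per overlap group.

    Two buffers of radius r overlap when the center distance is strictly
    below 2r. Overlap is chained into connected components
    (single-linkage), and exactly one record per component is kept,
    chosen uniformly at random with the given seed. The retained count is
    therefore seed-independent; only the representatives vary.
    """
    if buffer_radius <= 0:
        raise ValueError("buffer_radius must be positive")
    if len(occ) == 0:
        return OccurrenceSet(records=[], thinned=True, thin_radius=buffer_radius)
    xy = occ.xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(2.0 * buffer_radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < 2.0 * buffer_radius]  # strict: touching buffers do not overlap
    comps = _connected_components(len(occ), pairs)
    rng = np.random.default_rng(seed)
    kept = sorted(comp[rng.integers(len(comp))] for comp in comps)
    return OccurrenceSet(
        records=[occ.records[i] for i in kept],
        thinned=True,
        thin_radius=buffer_radius,
    )
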