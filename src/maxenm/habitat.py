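"""Habitat mapping: replicate averaging, max-TSS binarization, area
accounting, zonal summaries, protected-area gap analysis and patch
fragmentation statistics.

Cells are assigned to zones by the center-point rule; areas are cell
counts times the cell area in km^2. Proportions are reported to 2
decimal places with half-up rounding, matching conventional table
formatting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec
from .zones import Zone, ZoneSet, zone_cell_mask


def round2(value: float) -> float:
    """Half-up rounding to 2 decimal places."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SuitabilityMap:
    spec: GridSpec
    values: np.ma.MaskedArray  # mean logistic suitability
    n_replicates: int = 1


@dataclass
class BinaryHabitatMap:
    spec: GridSpec
    suitable: np.ndarray  # boolean; False on masked cells
    threshold: float
    mask: np.ndarray | None = None  # nodata mask


@dataclass
class ZoneSummary:
    zone: str
    role: str
    zone_area_km2: float
    suitable_km2: float
    proportion_pct: float  # 100 * suitable / zone, 2 dp


@dataclass
class PatchStats:
    n_patches: int
    cell_counts: np.ndarray
    areas_km2: np.ndarray
    largest_patch_fraction: float
    connectivity: int


def average_replicates(grids: list, spec: GridSpec, n_replicates: int | None = None) -> SuitabilityMap:
    """Cell-wise arithmetic mean of replicate suitability grids (mask propagated)."""
    if not grids:
        raise ValueError("no grids to average")
    shape = (spec.n_rows, spec.n_cols)
    arrs = []
    for g in grids:
        g = np.ma.asarray(g)
        if g.shape != shape:
            raise ValueError(f"grid shape {g.shape} does not match spec {shape}")
        arrs.append(g)
    mean = np.ma.mean(np.ma.stack(arrs), axis=0)
    # a cell masked in any replicate is masked in the average
    anymask = np.zeros(shape, dtype=bool)
    for g in arrs:
        anymask |= np.ma.getmaskarray(g)
    mean = np.ma.masked_array(np.ma.filled(mean, 0.0), mask=anymask)
    return SuitabilityMap(spec, mean, n_replicates=n_replicates or len(grids))


def apply_threshold(suit: SuitabilityMap, threshold: float) -> BinaryHabitatMap:
    """Binary suitable/unsuitable map: suitable <=> suitability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.ma.getmaskarray(suit.values)
    suitable = np.ma.filled(suit.values >= threshold, False) & ~mask
    return BinaryHabitatMap(suit.spec, np.asarray(suitable, dtype=bool), threshold, mask=mask)


def habitat_area(bmap: BinaryHabitatMap) -> float:
    """Total suitable area in km^2 (cell count x cell area)."""
    return float(bmap.suitable.sum() * bmap.spec.cell_area_km2)


def zonal_summary(bmap: BinaryHabitatMap, zones: ZoneSet) -> list[ZoneSummary]:
    """Per-zone area accounting (center-point cell assignment).

    Overlapping zones each count their own cells; a zone entirely outside
    the grid extent yields a zero-area row with a warning.
    """
    out = []
    for z in zones.zones:
        inz = zone_cell_mask(z, bmap.spec)
        if not inz.any():
            warnings.warn(f"zone {z.name!r} contains no cell centers; zero-area row")
        if bmap.mask is not None:
            inz = inz & ~bmap.mask
        zone_area = float(inz.sum() * bmap.spec.cell_area_km2)
        suit_area = float((inz & bmap.suitable).sum() * bmap.spec.cell_area_km2)
        prop = round2(100.0 * suit_area / zone_area) if zone_area > 0 else 0.0
        out.append(ZoneSummary(z.name, z.role, zone_area, suit_area, prop))
    return out


def summaries_frame(summaries: list[ZoneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "zone": [s.zone for s in summaries],
            "role": [s.role for s in summaries],
            "zone_area_km2": [s.zone_area_km2 for s in summaries],
            "suitable_km2": [s.suitable_km2 for s in summaries],
            "proportion_pct": [s.proportion_pct for s in summaries],
        }
    )


def protected_fraction(bmap: BinaryHabitatMap, reserves: list[Zone]) -> float:
    """Percent of all suitable habitat inside the union of reserve zones.

    The union is computed cell-wise, so overlapping reserves are not
    double-counted. 2 dp, half-up.
    """
    total = habitat_area(bmap)
    if total <= 0:
        raise ValueError("no suitable habitat; protected fraction undefined")
    union = np.zeros_like(bmap.suitable, dtype=bool)
    for z in reserves:
        union |= zone_cell_mask(z, bmap.spec)
    inside = float((union & bmap.suitable).sum() * bmap.spec.cell_area_km2)
    return round2(100.0 * inside / total)


def patch_stats(bmap: BinaryHabitatMap, connectivity: int = 8) -> PatchStats:
    """Connected components of suitable cells (4- or 8-connectivity)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(bmap.suitable, structure=structure)
    counts = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)
    areas = counts * bmap.spec.cell_area_km2
    largest = float(counts.max() / counts.sum()) if n else 0.0
    return PatchStats(
        n_patches=int(n),
        cell_counts=counts,
        areas_km2=areas,
        largest_patch_fraction=largest,
        connectivity=connectivity,
    )
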