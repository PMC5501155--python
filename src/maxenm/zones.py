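"""Named administrative / protected-area polygons (counties, reserves)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

VALID_ROLES = ("county", "reserve", "region")


@dataclass
class Zone:
    name: str
    role: str  # county | reserve | region
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"zone role must be one of {VALID_ROLES}, got {self.role!r}")


@dataclass
class ZoneSet:
    zones: list[Zone] = field(default_factory=list)

    def __post_init__(self) -> None:
        for role in VALID_ROLES:
            names = [z.name for z in self.zones if z.role == role]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate zone names within role {role!r}")

    def __len__(self) -> int:
        return len(self.zones)

    def by_role(self, role: str) -> list[Zone]:
        return [z for z in self.zones if z.role == role]


def read_zones(path) -> ZoneSet:
    """Read a GeoJSON FeatureCollection with properties ``name`` and ``role``."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise IOError(f"{path}: expected a GeoJSON FeatureCollection")
    zones = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {}) or {}
        zones.append(
            Zone(
                name=str(props.get("name", f"zone{len(zones)}")),
                role=str(props.get("role", "region")),
                geometry=shape(feat["geometry"]),
            )
        )
    return ZoneSet(zones)


def write_zones(zones: ZoneSet, path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": z.name, "role": z.role},
                "geometry": mapping(z.geometry),
            }
            for z in zones.zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def zone_cell_mask(zone: Zone, spec) -> np.ndarray:
    """Boolean grid of cells whose CENTER falls inside the zone polygon."""
    X, Y = spec.cell_centers()
    return shapely.contains_xy(zone.geometry, X.ravel(), Y.ravel()).reshape(X.shape)
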