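"""Protected-area gap analysis.

Intersects the binary habitat map with the county and reserve
polygons: per-zone suitable area and proportion, plus the fraction of
all suitable habitat inside the reserve-network union (habitat outside
it is the conservation gap).
"""

import argparse
import os

import numpy as np

from maxenm import protected_fraction, zonal_summary
from maxenm.grids import read_ascii_grid
from maxenm.habitat import BinaryHabitatMap, habitat_area, summaries_frame
from maxenm.zones import read_zones


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--landscape", default="results/landscape")
    ap.add_argument("--habitat", default="results/habitat")
    ap.add_argument("--out", default="results/gap")
    args = ap.parse_args()

    spec, layer = read_ascii_grid(os.path.join(args.habitat, "habitat_binary.asc"))
    bmap = BinaryHabitatMap(
        spec,
        np.ma.filled(layer.values, 0.0) > 0.5,
        threshold=float("nan"),
        mask=np.ma.getmaskarray(layer.values),
    )
    zones = read_zones(os.path.join(args.landscape, "zones.geojson"))

    rows = zonal_summary(bmap, zones)
    os.makedirs(args.out, exist_ok=True)
    summaries_frame(rows).to_csv(os.path.join(args.out, "zone_summaries.csv"), index=False)

    print(f"{'zone':<14}{'role':<10}{'area km2':>10}{'suitable':>10}{'pct':>8}")
    for s in rows:
        print(f"{s.zone:<14}{s.role:<10}{s.zone_area_km2:>10.1f}{s.suitable_km2:>10.1f}{s.proportion_pct:>8.2f}")
    reserves = zones.by_role("reserve")
    total = habitat_area(bmap)
    frac = protected_fraction(bmap, reserves)
    print(f"\ntotal suitable habitat: {total:.1f} km^2")
    print(f"inside reserve network: {frac:.2f}% (conservation gap: {100 - frac:.2f}%)")


if __name__ == "__main__":
    main()
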