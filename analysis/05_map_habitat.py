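"""Binary habitat map and fragmentation.

Thresholds the replicate-mean suitability grid at the mean max-TSS
threshold, writes the binary suitable/unsuitable map and reports total
suitable area and patch structure (8-connectivity).
"""

import argparse
import json
import os

import numpy as np

from maxenm import apply_threshold, habitat_area, patch_stats
from maxenm.grids import Layer, read_ascii_grid, write_ascii_grid
from maxenm.habitat import SuitabilityMap


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--evaluation", default="results/evaluation")
    ap.add_argument("--out", default="results/habitat")
    args = ap.parse_args()

    spec, mean_layer = read_ascii_grid(os.path.join(args.evaluation, "suitability_mean.asc"))
    with open(os.path.join(args.evaluation, "summary.json")) as fh:
        threshold = json.load(fh)["mean_tss_threshold"]

    bmap = apply_threshold(SuitabilityMap(spec, mean_layer.values), threshold)
    os.makedirs(args.out, exist_ok=True)
    write_ascii_grid(
        os.path.join(args.out, "habitat_binary.asc"),
        spec,
        Layer("habitat_binary", np.ma.masked_array(bmap.suitable.astype(float), mask=bmap.mask)),
    )
    total = habitat_area(bmap)
    stats = patch_stats(bmap, connectivity=8)
    region_km2 = spec.n_rows * spec.n_cols * spec.cell_area_km2
    with open(os.path.join(args.out, "summary.json"), "w") as fh:
        json.dump(
            {
                "threshold": threshold,
                "suitable_km2": total,
                "region_km2": region_km2,
                "suitable_pct": 100.0 * total / region_km2,
                "n_patches": stats.n_patches,
                "largest_patch_fraction": stats.largest_patch_fraction,
            },
            fh,
            indent=1,
        )

    print(f"max-TSS threshold: {threshold:.3f}")
    print(f"suitable habitat: {total:.1f} km^2 of {region_km2:.0f} km^2 "
          f"({100 * total / region_km2:.2f}% of the region)")
    print(f"fragmentation: {stats.n_patches} patches, "
          f"largest holds {100 * stats.largest_patch_fraction:.1f}% of suitable area")


if __name__ == "__main__":
    main()
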