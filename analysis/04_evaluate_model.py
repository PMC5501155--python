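"""Replicate evaluation of the selected model.

Generates 200 pseudo-absences outside 1 km presence buffers, runs 20
random 75/25 train/test replicates of the winning variable set, and
reports training/test AUC against background plus maximized Kappa and
TSS against the pseudo-absences, with their performance labels.
"""

import argparse
import json
import os

import numpy as np

from maxenm import (
    bootstrap_evaluate,
    build_features,
    generate_pseudo_absences,
    performance_class,
    sample_background,
    stage_seed,
)
from maxenm.grids import load_stack, write_ascii_grid, Layer
from maxenm.habitat import average_replicates
from maxenm.maxent import merge_presences_into_background
from maxenm.occurrences import read_occurrences


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--landscape", default="results/landscape")
    ap.add_argument("--thinned", default="results/thinning/occurrences_thinned.csv")
    ap.add_argument("--selection", default="results/selection")
    ap.add_argument("--out", default="results/evaluation")
    args = ap.parse_args()

    with open(os.path.join(args.landscape, "manifest.json")) as fh:
        manifest = json.load(fh)
    layer_names = (
        [r["variable"] for r in manifest["informative"]]
        + list(manifest["duplicates"])
        + manifest["noise"]
    )
    stack = load_stack(
        [os.path.join(args.landscape, f"{n}.asc") for n in layer_names], names=layer_names
    )
    occ = read_occurrences(args.thinned)
    with open(os.path.join(args.selection, "winner.json")) as fh:
        winner = json.load(fh)["winner"]

    xy = occ.xy
    r, c = stack.spec.index_of(xy[:, 0], xy[:, 1])
    bg = sample_background(stack, n=10000, seed=stage_seed(args.seed, "background"))
    bg = merge_presences_into_background(bg, r, c, stack)
    expansion = build_features(bg.table, n_presences=len(occ))
    pa = generate_pseudo_absences(stack, occ, n=200, seed=stage_seed(args.seed, "pseudo_absences"))

    summary = bootstrap_evaluate(
        stack, winner, occ, pa, bg, expansion, reps=20, seed=stage_seed(args.seed, "evaluate")
    )
    os.makedirs(args.out, exist_ok=True)
    summary.to_frame().to_csv(os.path.join(args.out, "replicates.csv"), index=False)
    summary.save_json(os.path.join(args.out, "summary.json"))
    np.savetxt(
        os.path.join(args.out, "pseudo_absences.csv"), pa, delimiter=",", header="x,y", comments=""
    )
    mean_map = average_replicates([rep.prediction for rep in summary.replicates], stack.spec)
    write_ascii_grid(
        os.path.join(args.out, "suitability_mean.asc"),
        stack.spec,
        Layer("suitability_mean", mean_map.values),
    )

    print(f"evaluated {len(winner)}-variable model over {len(summary.replicates)} replicates:")
    print(
        f"  training AUC {summary.mean_training_auc:.3f}"
        f" ({performance_class('auc', summary.mean_training_auc)})"
    )
    print(
        f"  test AUC     {summary.mean_test_auc:.3f}"
        f" ({performance_class('auc', summary.mean_test_auc)})"
    )
    print(
        f"  max Kappa    {summary.mean_max_kappa:.3f}"
        f" ({performance_class('kappa', summary.mean_max_kappa)})"
    )
    print(
        f"  max TSS      {summary.mean_max_tss:.3f}"
        f" ({performance_class('tss', summary.mean_max_tss)})"
    )
    print(f"  mean max-TSS threshold {summary.mean_tss_threshold:.3f}")


if __name__ == "__main__":
    main()
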