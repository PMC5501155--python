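"""Stepwise AICc variable selection.

Fits the full-variable model, iteratively screens against the t-th
highest contributor (removing variables with contribution < 1% or
|Pearson r| > 0.7 with the screening variable), scores every candidate
by landscape-standardized AICc, and reports whether the winner
recovered the planted truth.
"""

import argparse
import json
import os

from maxenm import select_variables
from maxenm.grids import load_stack
from maxenm.occurrences import read_occurrences


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--landscape", default="results/landscape")
    ap.add_argument("--thinned", default="results/thinning/occurrences_thinned.csv")
    ap.add_argument("--out", default="results/selection")
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

    trace = select_variables(stack, occ, seed=args.seed)
    os.makedirs(args.out, exist_ok=True)
    trace.save_json(os.path.join(args.out, "selection_trace.json"))
    trace.to_frame().to_csv(os.path.join(args.out, "selection_trace.csv"), index=False)

    for c in trace.candidates:
        mark = " <- winner" if c is trace.winner else ""
        aicc = f"{c.aicc:.1f}" if c.aicc_valid else "invalid"
        print(f"model {c.step}: {len(c.variables)} variables, k={c.k}, AICc={aicc}{mark}")
    print(f"winner variables: {', '.join(trace.winner.variables)}")
    with open(os.path.join(args.out, "winner.json"), "w") as fh:
        json.dump({"winner": trace.winner.variables}, fh, indent=1)


if __name__ == "__main__":
    main()
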