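"""End-to-end orchestration: thin -> select -> evaluate -> map -> zones.

A single master seed deterministically derives one seed per stage
(pure function of master seed and stage name), so a run is exactly
reproducible from its configuration; every intermediate artifact is
persisted so the report numbers can be recomputed from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import habitat
from .evaluation import bootstrap_evaluate, generate_pseudo_absences, performance_class
from .features import build_features
from .grids import Layer, RasterStack, load_stack, write_ascii_grid
from .maxent import merge_presences_into_background, sample_background
from .occurrences import ONE_KM2_RADIUS, OccurrenceSet, read_occurrences, thin_occurrences, write_occurrences
from .selection import select_variables
from .zones import ZoneSet, read_zones

log = logging.getLogger("maxenm")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of the workflow, with the standard defaults.

    Defaults follow common practice for this kind of analysis: 1 km^2
    circular thinning buffer, correlation cutoff |r| = 0.7 and
    contribution cutoff 1%, regularization multiplier 1, up to 10,000
    background points, 500 iterations at convergence tolerance 1e-5,
    20 replicates at a 75/25 split, 200 pseudo-absences outside 1 km
    buffers, and a 0.001 threshold scan step.
    """

    # inputs
    stack_paths: list = field(default_factory=list)
    stack_names: list | None = None
    stack_kinds: list | None = None
    occurrences_path: str | None = None
    zones_path: str | None = None
    output_dir: str = "maxenm_run"
    # thinning
    thin_radius: float = ONE_KM2_RADIUS
    # selection
    r_cut: float = 0.7
    c_cut: float = 1.0
    rank_from: str = "current"
    # maxent
    reg_multiplier: float = 1.0
    background_n: int = 10000
    max_iter: int = 500
    tol: float = 1e-5
    hinge_knots: int = 50
    presences_in_background: bool = True
    # evaluation
    reps: int = 20
    train_frac: float = 0.75
    n_pseudo_absences: int = 200
    pa_exclusion_radius: float = 1000.0
    threshold_step: float = 0.001
    replicate_mode: str = "split"
    # habitat
    patch_connectivity: int = 8
    # master seed (all stage seeds derive from it)
    seed: int = 20170705

    def validate(self) -> None:
        if not 0 < self.r_cut <= 1:
            raise ValueError("r_cut must lie in (0, 1]")
        if not 0 <= self.c_cut <= 100:
            raise ValueError("c_cut must lie in [0, 100]")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.thin_radius <= 0 or self.pa_exclusion_radius <= 0:
            raise ValueError("radii must be positive")
        if self.replicate_mode not in ("split", "resample"):
            raise ValueError("replicate_mode must be 'split' or 'resample'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Summary of one full pipeline run; every number is recomputable
    from the artifacts persisted next to it."""

    config: dict
    n_occurrences_raw: int
    n_occurrences_thinned: int
    winner_variables: list
    winner_aicc: float
    n_candidates: int
    mean_training_auc: float
    mean_test_auc: float
    mean_max_kappa: float
    mean_max_tss: float
    threshold: float
    total_suitable_km2: float
    n_patches: int
    largest_patch_fraction: float
    performance: dict
    zone_summaries: list = field(default_factory=list)
    protected_fraction_pct: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            "maxenm pipeline report",
            "======================",
            f"occurrences: {self.n_occurrences_raw} raw -> {self.n_occurrences_thinned} after thinning",
            f"selection: {self.n_candidates} candidate models; winner AICc {self.winner_aicc:.2f}",
            f"winner variables: {', '.join(self.winner_variables)}",
            f"training AUC {self.mean_training_auc:.3f} ({self.performance['training_auc']}), "
            f"test AUC {self.mean_test_auc:.3f} ({self.performance['test_auc']})",
            f"max Kappa {self.mean_max_kappa:.3f} ({self.performance['kappa']}), "
            f"max TSS {self.mean_max_tss:.3f} ({self.performance['tss']})",
            f"max-TSS threshold {self.threshold:.3f}",
            f"suitable habitat {self.total_suitable_km2:.2f} km^2 in {self.n_patches} patches "
            f"(largest {100 * self.largest_patch_fraction:.1f}%)",
        ]
        if self.protected_fraction_pct is not None:
            lines.append(f"protected fraction {self.protected_fraction_pct:.2f}%")
        return "\n".join(lines) + "\n"


def _timed(stage: str, seed: int | None = None):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage=%s seed=%s start", stage, seed)
            return self

        def __exit__(self, *exc):
            log.info("stage=%s wall=%.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    stack: RasterStack | None = None,
    occurrences: OccurrenceSet | None = None,
    zones: ZoneSet | None = None,
) -> RunReport:
    """Execute the full workflow and persist all artifacts to output_dir."""
    config.validate()
    if stack is None:
        if not config.stack_paths:
            raise ValueError("config has no stack_paths and no stack was supplied")
        stack = load_stack(config.stack_paths, config.stack_names, config.stack_kinds)
    if occurrences is None:
        if config.occurrences_path is None:
            raise ValueError("config has no occurrences_path and no occurrences were supplied")
        occurrences = read_occurrences(config.occurrences_path)
    if zones is None and config.zones_path is not None:
        zones = read_zones(config.zones_path)

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "config.yaml"))

    with _timed("thin", stage_seed(config.seed, "thin")):
        thinned = thin_occurrences(occurrences, config.thin_radius, seed=stage_seed(config.seed, "thin"))
        write_occurrences(thinned, os.path.join(out, "occurrences_thinned.csv"))

    xy = thinned.xy
    prow, pcol = stack.spec.index_of(xy[:, 0], xy[:, 1])
    with _timed("background", stage_seed(config.seed, "background")):
        bg = sample_background(stack, n=config.background_n, seed=stage_seed(config.seed, "background"))
        if config.presences_in_background:
            bg = merge_presences_into_background(bg, prow, pcol, stack)

    with _timed("select", config.seed):
        trace = select_variables(
            stack,
            thinned,
            background_n=config.background_n,
            seed=stage_seed(config.seed, "background"),
            reg_multiplier=config.reg_multiplier,
            hinge_knots=config.hinge_knots,
            r_cut=config.r_cut,
            c_cut=config.c_cut,
            max_iter=config.max_iter,
            tol=config.tol,
            presences_in_background=config.presences_in_background,
            rank_from=config.rank_from,
            background=bg,
        )
        trace.save_json(os.path.join(out, "selection_trace.json"))
        trace.to_frame().to_csv(os.path.join(out, "selection_trace.csv"), index=False)

    with _timed("pseudo_absences", stage_seed(config.seed, "pseudo_absences")):
        pa = generate_pseudo_absences(
            stack,
            thinned,
            n=config.n_pseudo_absences,
            exclusion_radius=config.pa_exclusion_radius,
            seed=stage_seed(config.seed, "pseudo_absences"),
        )
        np.savetxt(
            os.path.join(out, "pseudo_absences.csv"),
            pa,
            delimiter=",",
            header="x,y",
            comments="",
            fmt="%.10g",
        )

    var_kinds = {l.name: l.kind for l in stack.layers}
    expansion = build_features(
        bg.table, var_kinds, n_presences=len(thinned), classes="auto", hinge_knots=config.hinge_knots
    )
    with _timed("evaluate", stage_seed(config.seed, "evaluate")):
        summary = bootstrap_evaluate(
            stack,
            trace.winner.variables,
            thinned,
            pa,
            bg,
            expansion,
            reps=config.reps,
            train_frac=config.train_frac,
            seed=stage_seed(config.seed, "evaluate"),
            threshold_step=config.threshold_step,
            replicate_mode=config.replicate_mode,
            reg_multiplier=config.reg_multiplier,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        summary.to_frame().to_csv(os.path.join(out, "evaluation_replicates.csv"), index=False)
        summary.save_json(os.path.join(out, "evaluation_summary.json"))

    with _timed("habitat"):
        mean_map = habitat.average_replicates(
            [r.prediction for r in summary.replicates], stack.spec
        )
        write_ascii_grid(
            os.path.join(out, "suitability_mean.asc"),
            stack.spec,
            Layer("suitability_mean", mean_map.values),
        )
        threshold = summary.mean_tss_threshold
        bmap = habitat.apply_threshold(mean_map, threshold)
        write_ascii_grid(
            os.path.join(out, "habitat_binary.asc"),
            stack.spec,
            Layer(
                "habitat_binary",
                np.ma.masked_array(bmap.suitable.astype(float), mask=bmap.mask),
            ),
        )
        total = habitat.habitat_area(bmap)
        patches = habitat.patch_stats(bmap, connectivity=config.patch_connectivity)

    zone_rows: list = []
    protected = None
    if zones is not None and len(zones) > 0:
        with _timed("zones"):
            summaries = habitat.zonal_summary(bmap, zones)
            habitat.summaries_frame(summaries).to_csv(
                os.path.join(out, "zone_summaries.csv"), index=False
            )
            zone_rows = [asdict(s) for s in summaries]
            reserves = zones.by_role("reserve")
            if reserves and total > 0:
                protected = habitat.protected_fraction(bmap, reserves)

    report = RunReport(
        config=asdict(config),
        n_occurrences_raw=len(occurrences),
        n_occurrences_thinned=len(thinned),
        winner_variables=list(trace.winner.variables),
        winner_aicc=trace.winner.aicc,
        n_candidates=len(trace.candidates),
        mean_training_auc=summary.mean_training_auc,
        mean_test_auc=summary.mean_test_auc,
        mean_max_kappa=summary.mean_max_kappa,
        mean_max_tss=summary.mean_max_tss,
        threshold=threshold,
        total_suitable_km2=total,
        n_patches=patches.n_patches,
        largest_patch_fraction=patches.largest_patch_fraction,
        performance={
            "training_auc": performance_class("auc", summary.mean_training_auc),
            "test_auc": performance_class("auc", summary.mean_test_auc),
            "kappa": performance_class("kappa", summary.mean_max_kappa),
            "tss": performance_class("tss", summary.mean_max_tss),
        },
        zone_summaries=zone_rows,
        protected_fraction_pct=protected,
    )
    report.save_json(os.path.join(out, "report.json"))
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(report.to_text())
    return report
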