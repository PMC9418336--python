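"""End-to-end orchestration: simulate -> coregister -> tsnoise -> features
-> learn -> classify -> validate -> aggregate, driven by one config.

Every stage draws from a seed derived from the single run seed, every
artifact is stamped with a hash of the config, and a JSON-lines log
records stage timings and headline numbers, so a run is reproducible
bit-for-bit from its config file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import aggregation, coregistration, features, io, learning
from . import synthetic, tsnoise, validation
from .core import CLASS_NAMES, DEFAULT_PIXEL_SIZE, ClassMap


@dataclass
class RunConfig:
    """Schema-validated configuration of a full synthetic run."""

    extent: int = 256
    seed: int = 7
    pixel_size: float = DEFAULT_PIXEL_SIZE
    mean_field_area_m2: float = 5000.0
    max_shift_px: float = 3.0
    cloud_fraction: float = 0.1
    noise_sd: float = 0.03
    # coregistration
    max_offset_m: float = 100.0
    stiffness: float = 5.0
    pyramid_levels: int = 3
    block_size: int = 64
    tile_size: int | None = None
    # learning
    n_trees: int = 250
    initial_per_class: int = 30
    augment_per_class: int = 50
    margin_quantile: float = 0.25
    min_dist_m: float = 50.0
    # validation design
    se_target: float = 0.01
    ua_assumed: float = 0.75
    per_class_floor: int = 30
    # aggregation
    cell_size_px: int = 32

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    truth: synthetic.SceneTruth
    classified: ClassMap
    estimate: validation.ErrorMatrixEstimate
    noise_before: float
    noise_after: float
    history: list = field(default_factory=list)
    grid_summary: object = None
    report: dict = field(default_factory=dict)


def run_end_to_end(cfg: RunConfig, outdir=None,
                   coregister: bool = True) -> RunResult:
    """Run the full pipeline on a synthetic scene; optionally write
    artifacts (class map, reports, log) under ``outdir``."""
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(s) for name, s in zip(
        ("scene", "render", "samples", "learn", "validate"),
        rng.integers(0, 2**31 - 1, 5))}
    log: list[dict] = []

    def stage(name, **info):
        log.append({"stage": name, "time": time.time(), **info})

    truth = synthetic.make_scene(
        cfg.extent, mean_field_area_m2=cfg.mean_field_area_m2,
        max_shift_px=cfg.max_shift_px, cloud_fraction=cfg.cloud_fraction,
        pixel_size=cfg.pixel_size, seed=seeds["scene"])
    series = synthetic.render_monthly_series(truth, noise_sd=cfg.noise_sd,
                                             seed=seeds["render"])
    stage("simulate", extent=cfg.extent)

    noise_before = tsnoise.noise_map(series).mean()
    if coregister:
        coreg_cfg = coregistration.CoregConfig(
            max_offset_m=cfg.max_offset_m, stiffness=cfg.stiffness,
            levels=cfg.pyramid_levels, block_size=cfg.block_size,
            pixel_size=cfg.pixel_size, tile_size=cfg.tile_size)
        series, fields = coregistration.coregister_series(series, coreg_cfg)
    noise_after = tsnoise.noise_map(series).mean()
    stage("coregister", enabled=coregister, tsnoise_before=noise_before,
          tsnoise_after=noise_after)

    stack = features.assemble_stack(series, truth.dem)
    stage("features", n_layers=len(stack.names))

    initial_pts = synthetic.sample_reference_points(
        truth, cfg.initial_per_class, min_dist_m=cfg.min_dist_m,
        seed=seeds["samples"])
    rows = np.array([s.row for s in initial_pts])
    cols = np.array([s.col for s in initial_pts])
    labels = np.array([s.class_code for s in initial_pts])
    initial = learning.TrainingSet(
        stack.values_at(rows, cols), labels, rows, cols,
        np.full(len(labels), "initial", dtype=object))

    def truth_labeler(rr, cc):
        return truth.class_map.codes[rr, cc].astype(int)

    lcfg = learning.LearnerConfig(
        n_trees=cfg.n_trees, margin_quantile=cfg.margin_quantile,
        augment_per_class=cfg.augment_per_class,
        min_dist_px=cfg.min_dist_m / cfg.pixel_size, seed=seeds["learn"])
    result = learning.run_active_learning(stack, initial, truth_labeler, lcfg)
    prob = learning.predict_probabilities(result.model, stack)
    classified = learning.classify(prob, pixel_size=cfg.pixel_size)
    stage("classify", n_training=len(result.training))

    shares = classified.empirical_proportions()
    present = sorted(shares)
    weights = np.array([shares[c] for c in present])
    n = validation.sample_size(weights, cfg.ua_assumed, cfg.se_target)
    # keep the design feasible on small synthetic maps
    n = min(n, classified.codes.size // 4)
    floor = min(cfg.per_class_floor,
                min(int(np.count_nonzero(classified.codes == c))
                    for c in present))
    n = max(n, floor * len(present))
    alloc = validation.allocate(n, weights, per_class_floor=floor)
    alloc = {c: min(int(a), int(np.count_nonzero(classified.codes == c)))
             for c, a in zip(present, alloc)}
    sample = validation.draw_validation_sample(classified, alloc,
                                               seed=seeds["validate"])
    ref = truth.class_map.codes[sample["row"], sample["col"]]
    k = len(present)
    code_idx = {c: i for i, c in enumerate(present)}
    counts = np.zeros((k, k))
    for mc, rc in zip(sample["map_class"], ref):
        if rc in code_idx:
            counts[code_idx[mc], code_idx[rc]] += 1
    est = validation.error_matrix_from_counts(counts, weights,
                                              class_codes=present)
    stage("validate", n_samples=int(sample.shape[0]),
          overall_accuracy=est.overall_accuracy)

    grid = aggregation.gridcell_fractions(classified, cfg.cell_size_px)
    stage("aggregate", n_cells=int(grid.shape[0]))

    report = {
        "config_hash": cfg.config_hash(),
        "tsnoise_before": noise_before,
        "tsnoise_after": noise_after,
        "overall_accuracy": est.overall_accuracy,
        "area_shares": {CLASS_NAMES[int(c)]: float(a)
                        for c, a in zip(est.class_codes, est.area_shares)},
        "map_fallow_share_of_cropland":
            aggregation.fallow_share_of_cropland(classified),
        "history": result.history,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_class_map(outdir / "classified.tif", classified)
        io.write_class_map(outdir / "truth.tif", truth.class_map)
        grid.to_csv(outdir / "grid_summary.csv", index=False)
        est.summary().to_csv(outdir / "accuracy.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        with open(outdir / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")

    return RunResult(cfg, truth, classified, est, noise_before, noise_after,
                     history=result.history, grid_summary=grid,
                     report=report)
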