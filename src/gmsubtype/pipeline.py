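"""End-to-end reproducible pipeline run.

``run_pipeline`` sequences the analysis stages — simulate/load,
residualize, cluster, importance, stability, characterize,
longitudinal — writes every stage's outputs plus a run manifest, and
expands a single global seed into per-stage seeds with a deterministic
scheme (``numpy.random.SeedSequence(seed).generate_state``), so each
stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import rfclust, stats as gstats
from .longitudinal import plot_trajectories, trajectory_contrasts
from .model import SubtypeModel
from .schema import ROISchema, default_schema
from .simulate import SimulationSpec, simulate_cohort

log = logging.getLogger("gmsubtype")

STAGES = ("cohort", "residualize", "cluster", "importance", "stability",
          "characterize", "longitudinal")

DEFAULT_CONFIG = {
    "simulate": True,
    "input": None,             # cohort CSV when simulate is False
    "schema": None,            # schema JSON; default canonical schema
    "seed": 0,
    "n_trees": rfclust.DEFAULT_N_TREES,
    "forest_repeats": rfclust.DEFAULT_FOREST_REPEATS,
    "k_min": 2,
    "k_max": 10,
    "covariates": ["center", "icv"],
    "dissimilarity_transform": "sqrt",
    "top_k": 10,
    "stability_repeats": 100,
    "adjust_for_wmh": False,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s % (2 ** 31)) for stage, s in zip(STAGES, state)}


def run_pipeline(config: dict | None = None, out_dir="gmsubtype_run") -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    On stage failure, partial outputs are preserved under
    ``out_dir/failed/`` and a :class:`PipelineError` naming the stage
    is raised.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest: dict = {"config": {k: v for k, v in cfg.items()},
                      "seed_ledger": seeds,
                      "package_version": pkg_version("gmsubtype"),
                      "stages": [], "runtimes_s": {}, "outputs": {},
                      "input_hashes": {}}
    schema = (ROISchema.from_json(cfg["schema"]) if cfg["schema"]
              else default_schema())

    current = "cohort"
    try:
        outputs: dict = {}
        t0 = time.perf_counter()
        if cfg["simulate"]:
            spec = SimulationSpec(seed=seeds["cohort"])
            cohort = simulate_cohort(spec, schema)
            gio.write_cohort(cohort, out / "cohort.csv", spec=spec)
        else:
            if not cfg["input"]:
                raise ValueError("config 'input' required when simulate is False")
            manifest["input_hashes"][cfg["input"]] = gio.file_sha256(cfg["input"])
            cohort = gio.read_cohort(cfg["input"], schema)
        _done(manifest, "cohort", t0)

        current = "residualize"
        t0 = time.perf_counter()
        model = SubtypeModel(
            cohort, schema, covariates=cfg["covariates"],
            n_trees=int(cfg["n_trees"]),
            forest_repeats=int(cfg["forest_repeats"]),
            k_range=range(int(cfg["k_min"]), int(cfg["k_max"]) + 1),
            dissimilarity_transform=cfg["dissimilarity_transform"],
            top_k=int(cfg["top_k"]))
        residuals = model.residualize()
        residuals.to_csv(out / "residuals.csv")
        _done(manifest, "residualize", t0)

        current = "cluster"
        t0 = time.perf_counter()
        results = model.fit(seed=seeds["cluster"])
        gio.write_matrix(results.proximity.values, out / "proximity.csv",
                         labels=cohort["subject_id"])
        (out / "dendrogram.newick").write_text(
            results.tree.to_newick(list(cohort["subject_id"])))
        results.solution.ch_table().to_csv(out / "ch_curve.csv", index=False)
        pd.DataFrame({"subject_id": cohort["subject_id"],
                      "cluster": results.labels}).to_csv(
            out / "labels.csv", index=False)
        _done(manifest, "cluster", t0)
        log.info("chosen K = %d", results.chosen_k)

        current = "importance"
        t0 = time.perf_counter()
        results.importance.to_frame().to_csv(out / "importance.csv", index=False)
        results.discrimination.separation_table().to_csv(
            out / "discrimination.csv", index=False)
        _done(manifest, "importance", t0)

        current = "stability"
        t0 = time.perf_counter()
        stability = results.stability(n_repeats=int(cfg["stability_repeats"]))
        stability.to_frame().to_csv(out / "stability.csv", index=False)
        _done(manifest, "stability", t0)

        current = "characterize"
        t0 = time.perf_counter()
        battery = results.characterize()
        gstats.comparison_frame(battery).to_csv(out / "table1.csv", index=False)
        results.ancova().to_csv(out / "ancova.csv")
        ratio = results.bg_ratio()
        ratio.cluster_stats.to_csv(out / "ratio.csv", index=False)
        zprof = results.z_profile()
        zprof.to_csv(out / "zprofile.csv")
        zprof.mask_table().to_csv(out / "zprofile_mask.csv", index=False)
        _done(manifest, "characterize", t0)

        current = "longitudinal"
        t0 = time.perf_counter()
        lmm = results.longitudinal(adjust_for_wmh=bool(cfg["adjust_for_wmh"]))
        lmm.fixed_effects.to_csv(out / "lmm_fixed.csv",
                                 index_label="term",
                                 float_format=gio.FLOAT_FORMAT)
        lmm.emm.to_csv(out / "emm.csv", index=False,
                       float_format=gio.FLOAT_FORMAT)
        trajectory_contrasts(lmm).to_csv(out / "contrasts.csv", index=False,
                                         float_format=gio.FLOAT_FORMAT)
        plot_trajectories(lmm, out / "trajectories.png")
        _done(manifest, "longitudinal", t0)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        raise PipelineError(current, exc) from exc

    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest["outputs"][f.name] = gio.file_sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=gio._jsonable))
    return manifest


def _done(manifest: dict, stage: str, t0: float) -> None:
    manifest["stages"].append(stage)
    manifest["runtimes_s"][stage] = round(time.perf_counter() - t0, 3)
    log.info("stage %s done (%.2fs)", stage, manifest["runtimes_s"][stage])
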