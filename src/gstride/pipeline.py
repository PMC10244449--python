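"""End-to-end pipeline wiring: simulate -> process -> summarize -> stats -> classify.

A pipeline run is described by a YAML file with a ``pipeline`` section
(stages, seed, output directory) and an optional ``run`` section holding
the processing :class:`~gstride.config.RunConfig`.  Every random draw is
controlled by the single top-level seed plus fixed per-stage offsets, all
recorded in the manifest, so re-running a manifest reproduces the numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (build_features, compare_classifiers, make_splits,
                       svm_cross_validate, tug_threshold_baseline)
from .config import RunConfig, _from_mapping
from .ins import detect_stance, run_zupt_ekf
from .io import (read_cohort_csv, read_imu_csv, write_cohort_csv, write_imu_csv,
                 write_stance_csv, write_stride_table, write_summary_json,
                 write_trajectory_csv)
from .metrics import strides_from_trajectory, summarize
from .simulate import (CohortSimConfig, GaitProfile, NoiseModel, synth_cohort,
                       synth_imu, synth_trajectory)
from .stats import correlation_matrix, describe_by_group, icc_consistency

log = logging.getLogger(__name__)

STAGES = ("simulate", "process", "summarize", "stats", "classify")
# fixed per-stage seed offsets recorded in the manifest
STAGE_SEED_OFFSET = {"simulate": 0, "classify": 1000}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _dataclass_from(cfg_cls, data: dict | None):
    data = data or {}
    names = {f.name for f in dataclasses.fields(cfg_cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cfg_cls.__name__} keys: {sorted(unknown)}")
    return cfg_cls(**data)


def load_pipeline_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"pipeline", "run"}
    if unknown:
        raise ValueError(f"unknown top-level config sections: {sorted(unknown)}")
    pipe = raw.get("pipeline", {})
    allowed = {"stages", "seed", "outdir", "imu_csv", "cohort_csv", "profile",
               "noise", "cohort", "classify"}
    unknown = set(pipe) - allowed
    if unknown:
        raise ValueError(f"unknown pipeline keys: {sorted(unknown)}")
    stages = pipe.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    run_cfg = _from_mapping(RunConfig, raw.get("run", {})).validate()
    return {"pipeline": pipe, "stages": stages, "run": run_cfg}


def run_pipeline(config_path: str | Path) -> dict:
    """Execute the configured stages in order and write a manifest.

    Any stage failure aborts the run; partially written outputs keep a
    ``.partial`` suffix.
    """
    cfg = load_pipeline_config(config_path)
    pipe = cfg["pipeline"]
    run_cfg: RunConfig = cfg["run"]
    stages: list[str] = [s for s in STAGES if s in cfg["stages"]]
    seed = int(pipe.get("seed", 0))
    outdir = Path(pipe.get("outdir", "gstride_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_path": str(config_path),
        "seed": seed,
        "stage_seed_offsets": STAGE_SEED_OFFSET,
        "stages": {},
    }
    processed = None  # (rec, mask, traj) handed from process to summarize

    def record(stage: str, **info):
        manifest["stages"][stage] = info

    imu_csv = pipe.get("imu_csv")
    cohort_csv = pipe.get("cohort_csv")

    for stage in stages:
        try:
            if stage == "simulate":
                profile = _dataclass_from(GaitProfile, pipe.get("profile")).validate()
                noise = _dataclass_from(NoiseModel, pipe.get("noise"))
                noise.seed = seed + STAGE_SEED_OFFSET["simulate"]
                truth = synth_trajectory(profile)
                rec = synth_imu(truth, noise)
                imu_csv = outdir / "imu.csv"
                write_imu_csv(rec, imu_csv)
                write_trajectory_csv(
                    _truth_traj(truth), outdir / "truth_trajectory.csv")
                write_stride_table(truth.true_strides, outdir / "truth_strides.csv")
                cohort_cfg = _dataclass_from(CohortSimConfig, pipe.get("cohort"))
                cohort_cfg.seed = seed + STAGE_SEED_OFFSET["simulate"]
                cohort = synth_cohort(cohort_cfg.validate())
                cohort_csv = outdir / "cohort.csv"
                write_cohort_csv(cohort, cohort_csv)
                record(stage, imu_csv=str(imu_csv), cohort_csv=str(cohort_csv),
                       n_samples=len(rec), n_true_strides=len(truth.true_strides),
                       n_subjects=len(cohort))
            elif stage == "process":
                if imu_csv is None:
                    raise ValueError("no IMU input: simulate first or set imu_csv")
                rec = read_imu_csv(imu_csv, run_cfg)
                mask = detect_stance(rec, run_cfg)
                traj = run_zupt_ekf(rec, mask, run_cfg)
                traj_path = outdir / "trajectory.csv"
                stance_path = outdir / "stance.csv"
                write_trajectory_csv(traj, traj_path)
                write_stance_csv(mask, stance_path)
                processed = (rec, mask, traj)
                record(stage, trajectory=str(traj_path), stance=str(stance_path),
                       n_samples=len(rec), n_stance_intervals=len(mask.intervals))
            elif stage == "summarize":
                if processed is None:
                    raise ValueError("summarize requires the process stage")
                rec, mask, traj = processed
                strides = strides_from_trajectory(traj, mask, rec.gyro, run_cfg)
                summary = summarize(strides)
                write_stride_table(strides, outdir / "strides.csv")
                write_summary_json(summary, outdir / "summary.json")
                record(stage, strides=str(outdir / "strides.csv"),
                       summary=str(outdir / "summary.json"), n_strides=len(strides))
            elif stage == "stats":
                if cohort_csv is None:
                    raise ValueError("no cohort input: simulate first or set cohort_csv")
                cohort = read_cohort_csv(cohort_csv)
                rows = []
                for var in ("Age", "Sex", "Speed_4m_walk", "TUG", "Velocity (m/s)"):
                    if var in cohort.columns:
                        d = describe_by_group(cohort, var)
                        rows.append({"variable": d.variable, "test": d.test, "p": d.p,
                                     "overall": str(d.overall),
                                     "nonfallers": str(d.nonfallers),
                                     "fallers": str(d.fallers)})
                import pandas as pd
                pd.DataFrame(rows).to_csv(outdir / "descriptives.csv", index=False)
                icc = icc_consistency(
                    cohort[["Speed_4m_walk", "Velocity (m/s)"]].to_numpy(float))
                with open(outdir / "icc.json", "w", encoding="utf-8") as fh:
                    json.dump({"icc": icc.icc, "F": icc.f_statistic,
                               "df": [icc.df1, icc.df2], "ci95": list(icc.ci95),
                               "p": icc.p, "band": icc.band}, fh, indent=2)
                corr = correlation_matrix(
                    cohort, ["Speed_4m_walk", "TUG", "SPPB_Total", "FES1"],
                    ["Velocity (m/s)", "StrideLength - SL (m)", "Cadence (steps/min)"])
                corr.r.to_csv(outdir / "correlations.csv")
                record(stage, descriptives=str(outdir / "descriptives.csv"),
                       icc=str(outdir / "icc.json"),
                       correlations=str(outdir / "correlations.csv"),
                       n_subjects=len(cohort))
            elif stage == "classify":
                if cohort_csv is None:
                    raise ValueError("no cohort input: simulate first or set cohort_csv")
                cohort = read_cohort_csv(cohort_csv)
                opts = pipe.get("classify", {}) or {}
                n_splits = int(opts.get("n_splits", 10))
                test_fraction = float(opts.get("test_fraction", 0.3))
                policy = opts.get("tug_policy", "fixed")
                cseed = seed + STAGE_SEED_OFFSET["classify"]
                features, labels = build_features(cohort)
                splits = make_splits(labels, n_splits, test_fraction, cseed)
                svm = svm_cross_validate(features, labels, seed=cseed,
                                         test_fraction=test_fraction, splits=splits)
                tug = tug_threshold_baseline(
                    cohort["TUG"].to_numpy(float), labels, policy=policy,
                    seed=cseed, test_fraction=test_fraction, splits=splits)
                comparison = compare_classifiers(svm, tug)
                out = {"svm": svm.to_dict(), "tug": tug.to_dict(),
                       "comparison": comparison}
                with open(outdir / "classification.json", "w", encoding="utf-8") as fh:
                    json.dump(out, fh, indent=2)
                record(stage, classification=str(outdir / "classification.json"),
                       svm_mean_accuracy=svm.mean_accuracy,
                       tug_mean_accuracy=tug.mean_accuracy)
        except Exception as exc:
            manifest["failed_stage"] = stage
            partial = outdir / "manifest.json.partial"
            with open(partial, "w", encoding="utf-8") as fh:
                json.dump(_clean(manifest), fh, indent=2)
            raise StageError(stage, exc) from exc

    manifest["run_config"] = dataclasses.asdict(run_cfg)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_clean(manifest), fh, indent=2)
    return manifest


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _truth_traj(truth):
    from .ins import NavTrajectory

    return NavTrajectory(t=truth.t, pos=truth.pos, vel=truth.vel, quat=truth.quat)
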