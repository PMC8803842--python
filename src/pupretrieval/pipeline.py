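"""Batch orchestration: preprocess -> features -> predict -> smooth -> score.

A :class:`RunConfig` lists trials (pose table, ROI config, metadata each),
the classifier bundles to apply, and parameter overrides. Each trial runs
the full chain at its own frame rate; a stage failure marks that trial
failed (with the stage name) without stopping the batch, and the summary
table always has one row per manifest entry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, features, preprocess, scoring
from .pose_io import PoseTrack, TrialMeta, read_pose_table, read_trial_meta
from .roi import ROIConfig, read_roi_config, roi_occupancy

log = logging.getLogger("pupretrieval")


class PipelineError(ValueError):
    pass


@dataclass
class TrialPaths:
    pose: str
    roi: str
    meta: str


@dataclass
class Overrides:
    """Analysis parameters; defaults are the documented protocol values."""

    movement_factor: float = 2.5
    location_factor: float = 4.0
    carry_window_s: float = 3.0
    reference_mm: Optional[float] = None  # None: use each trial's metadata
    max_trial_s: Optional[float] = None
    likelihood_floor: Optional[float] = None  # optional confidence filter, off by default

    def __post_init__(self) -> None:
        for v in (self.movement_factor, self.location_factor, self.carry_window_s):
            if v <= 0:
                raise PipelineError("override parameters must be positive")


@dataclass
class RunConfig:
    trials: List[TrialPaths]
    bundle_dirs: Dict[str, str]
    out_dir: str
    seed: int = 0
    overrides: Overrides = field(default_factory=Overrides)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            trials=[TrialPaths(**t) for t in d["trials"]],
            bundle_dirs=dict(d["bundles"]),
            out_dir=d["out_dir"],
            seed=int(d.get("seed", 0)),
            overrides=Overrides(**d.get("overrides", {})),
        )


def analyze_trial(track: PoseTrack, roi_cfg: ROIConfig, meta: TrialMeta,
                  bundles: Dict[str, classify.ClassifierBundle],
                  overrides: Overrides = Overrides()) -> scoring.RetrievalResult:
    """Run the analysis chain on one in-memory trial.

    Quality control and calibration, feature extraction, per-behavior
    prediction with minimum-bout smoothing, then retrieval scoring from the
    pup's nest occupancy and the smoothed carry labels.
    """
    if track.unit != "px":
        raise PipelineError("analyze_trial expects a pixel-unit track")
    if meta.calibration_px is None:
        raise PipelineError(f"trial {meta.trial_id}: metadata lacks calibration landmarks")
    ref_mm = overrides.reference_mm if overrides.reference_mm is not None \
        else meta.calibration_reference_mm
    max_trial_s = overrides.max_trial_s if overrides.max_trial_s is not None \
        else meta.max_trial_s

    if overrides.likelihood_floor is not None:
        track = preprocess.filter_low_likelihood(track, overrides.likelihood_floor)
    criteria = preprocess.compute_criteria(
        track, overrides.movement_factor, overrides.location_factor)
    corrected, report = preprocess.correct_outliers(track, criteria)
    log.info("trial %s: %d movement + %d location corrections",
             meta.trial_id, report.total_movement, report.total_location)

    calib = preprocess.calibrate(*meta.calibration_px, reference_mm=ref_mm)
    track_mm = preprocess.to_mm(corrected, calib)
    roi_mm = roi_cfg.scaled(calib.scale)

    fmat = features.extract_features(track_mm, roi_mm, fps=meta.fps)

    behavior_labels: Dict[str, np.ndarray] = {}
    for name, bundle in bundles.items():
        raw = classify.predict_frames(bundle, fmat)
        smooth = classify.enforce_min_bout(raw.values, bundle.min_bout_ms, meta.fps)
        behavior_labels[name] = smooth

    occupancy = roi_occupancy(track_mm, roi_mm, "pup", "any", "nest")
    return scoring.score_trial(
        meta.trial_id, occupancy, behavior_labels, meta.fps,
        carry_window_s=overrides.carry_window_s, max_trial_s=max_trial_s)


def run_trial_analysis(config: RunConfig) -> pd.DataFrame:
    """Run the chain for every trial in the manifest.

    Writes one JSON per trial plus a flat batch summary table
    (``summary.csv``) under ``config.out_dir``; returns the summary. Failed
    trials appear in the summary with their failing stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("batch of %d trials, seed %d, overrides %s",
             len(config.trials), config.seed, vars(config.overrides))

    bundles = {}
    for behavior, path in config.bundle_dirs.items():
        bundles[behavior] = classify.load_bundle(path)
        log.info("bundle %s: threshold %.2f, min bout %.0f ms, seed %d",
                 behavior, bundles[behavior].discrimination_threshold,
                 bundles[behavior].min_bout_ms, bundles[behavior].seed)

    rows = []
    for paths in config.trials:
        row: dict = {"pose": paths.pose, "status": "ok", "failed_stage": ""}
        stage = "read"
        try:
            meta = read_trial_meta(paths.meta)
            row["trial_id"] = meta.trial_id
            track = read_pose_table(paths.pose, fps=meta.fps)
            stage = "roi"
            roi_cfg = read_roi_config(paths.roi)
            stage = "analyze"
            result = analyze_trial(track, roi_cfg, meta, bundles, config.overrides)
            row.update(result.to_dict())
            with open(out_dir / f"{meta.trial_id}.json", "w") as fh:
                json.dump(result.to_dict(), fh, indent=2)
        except Exception as exc:  # noqa: BLE001 - fault isolation per trial
            row["status"] = "failed"
            row["failed_stage"] = stage
            row["error"] = str(exc)
            log.warning("trial %s failed at stage %s: %s", paths.pose, stage, exc)
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    return summary
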