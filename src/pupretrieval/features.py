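"""Per-frame feature matrix for behavior classification.

The classifiers consume a deterministic, versioned registry of kinematic
and ROI-relative features computed from a corrected, millimetre-calibrated
pose track:

* per-animal centroid position and its distance to the nest and core-nest
  centres;
* dam-nose to pup-centroid and centroid-to-centroid distances, and their
  frame-to-frame rate of change (relative speed);
* per-part frame displacement and the per-animal mean movement;
* animal extent (sum of pairwise within-animal part distances), a posture
  measure that oscillates during digging;
* boundary-inclusive in-nest / in-core-nest flags (any-part rule);
* rolling mean / median / std of each base feature over 0.2, 0.5 and 1.0 s
  windows (converted to frames, minimum one), with edge-replicated padding
  so every frame has a full window.

The matrix is a pure function of (track, roi, fps, windows); the registry
maps every column name to a formula string and carries a version hash that
trained classifier bundles record and verify at prediction time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .pose_io import PoseTrack
from .roi import ROIConfig, roi_occupancy

DEFAULT_WINDOWS_S: Tuple[float, ...] = (0.2, 0.5, 1.0)


class FeatureError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Frames x named-features table plus its formula registry."""

    data: pd.DataFrame
    registry: dict
    version: str
    fps: float
    windows_s: Tuple[float, ...]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def to_csv(self, path, registry_path=None) -> None:
        self.data.to_csv(path, index=False)
        if registry_path is not None:
            with open(registry_path, "w") as fh:
                json.dump(
                    {"version": self.version, "fps": self.fps,
                     "windows_s": list(self.windows_s), "features": self.registry},
                    fh, indent=2)


def _registry_version(registry: dict, windows_s: Sequence[float]) -> str:
    payload = json.dumps({"features": registry, "windows_s": list(windows_s)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def window_frames(window_s: float, fps: float) -> int:
    """Window length in frames: round(seconds * fps), at least 1."""
    return max(1, int(round(window_s * fps)))


def _rolling_stats(x: np.ndarray, w: int):
    """Centered rolling mean/median/std with edge-replicated padding."""
    if w <= 1:
        return x.copy(), x.copy(), np.zeros_like(x)
    left = w // 2
    right = w - 1 - left
    xp = np.pad(x, (left, right), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(xp, w)
    return win.mean(axis=1), np.median(win, axis=1), win.std(axis=1)


def _displacement(xy: np.ndarray) -> np.ndarray:
    """Frame-to-frame displacement, edge-replicated so frame 0 moves 0."""
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.concatenate([[0.0], d])


def extract_features(track_mm: PoseTrack, roi: ROIConfig, fps: float | None = None,
                     windows_s: Sequence[float] = DEFAULT_WINDOWS_S,
                     include_roi_features: bool = True) -> FeatureMatrix:
    """Build the classification feature matrix from a calibrated track.

    The track must be outlier-corrected and in millimetres, with the ROI in
    the same coordinate frame. Any non-finite coordinate is an error:
    preprocessing owes the classifier a complete track.

    ``include_roi_features`` controls the nest-relative columns (occupancy
    flags and distances to the nest/core centres). They are on by default
    for every behavior; digging is the one whose classification depends on
    them, so position-independent classifiers can be trained by turning
    them off.
    """
    if fps is None:
        fps = track_mm.fps
    if not np.isfinite(track_mm.coords[:, :, :2]).all():
        raise FeatureError("track contains non-finite coordinates; run outlier correction first")
    if track_mm.unit != "mm":
        raise FeatureError(f"track unit is {track_mm.unit!r}; calibrate to mm first")

    cols: dict = {}
    reg: dict = {}

    def add(name, values, formula):
        if name in cols:
            raise FeatureError(f"duplicate feature name {name!r}")
        cols[name] = np.asarray(values, dtype=float)
        reg[name] = formula

    animals = sorted({a for a, _ in track_mm.body_parts})
    centroids = {}
    for animal in animals:
        idx = track_mm.animal_indices(animal)
        xy = track_mm.coords[:, idx, :2]  # (frames, k, 2)
        centroid = xy.mean(axis=1)
        centroids[animal] = centroid
        add(f"{animal}_centroid_x", centroid[:, 0], f"mean x of {animal} parts [mm]")
        add(f"{animal}_centroid_y", centroid[:, 1], f"mean y of {animal} parts [mm]")

        disp = np.stack([_displacement(xy[:, j]) for j in range(xy.shape[1])], axis=1)
        for j, gi in enumerate(idx):
            a, p = track_mm.body_parts[gi]
            add(f"{a}_{p}_move", disp[:, j], f"frame displacement of {a} {p} [mm/frame]")
        add(f"{animal}_movement_mean", disp.mean(axis=1),
            f"mean frame displacement over {animal} parts [mm/frame]")

        k = xy.shape[1]
        iu, ju = np.triu_indices(k, 1)
        pair = np.linalg.norm(xy[:, iu] - xy[:, ju], axis=2).sum(axis=1)
        add(f"{animal}_extent", pair, f"sum of pairwise {animal} part distances [mm]")

        if include_roi_features:
            add(f"{animal}_in_nest",
                roi_occupancy(track_mm, roi, animal, "any", "nest").astype(float),
                f"1 if any {animal} part inside nest polygon (boundary inclusive)")
            add(f"{animal}_in_core_nest",
                roi_occupancy(track_mm, roi, animal, "any", "core_nest").astype(float),
                f"1 if any {animal} part inside core-nest circle (boundary inclusive)")
            add(f"{animal}_centroid_nest_dist",
                np.linalg.norm(centroid - roi.nest_center, axis=1),
                f"{animal} centroid to nest polygon centroid [mm]")
            add(f"{animal}_centroid_core_dist",
                np.linalg.norm(centroid - roi.core_nest.center, axis=1),
                f"{animal} centroid to core-nest centre [mm]")

    dam_nose = track_mm.xy("dam", "nose")
    nose_pup = np.linalg.norm(dam_nose - centroids["pup"], axis=1)
    add("dam_nose_pup_centroid_dist", nose_pup, "dam nose to pup centroid [mm]")
    cc = np.linalg.norm(centroids["dam"] - centroids["pup"], axis=1)
    add("dam_pup_centroid_dist", cc, "dam centroid to pup centroid [mm]")
    change = np.concatenate([[0.0], np.diff(cc)])
    add("dam_pup_relative_speed", np.abs(change),
        "abs frame change of dam-pup centroid distance [mm/frame]")
    add("dam_pup_closing_rate", -change,
        "signed closing rate of dam-pup centroid distance, positive when approaching [mm/frame]")

    base_names = list(cols.keys())
    for w_s in windows_s:
        w = window_frames(w_s, fps)
        for name in base_names:
            mean, med, std = _rolling_stats(cols[name], w)
            add(f"{name}_mean_{w_s:g}s", mean,
                f"centered rolling mean of {name} over round({w_s:g}*fps) frames, edge padded")
            add(f"{name}_median_{w_s:g}s", med,
                f"centered rolling median of {name} over round({w_s:g}*fps) frames, edge padded")
            add(f"{name}_std_{w_s:g}s", std,
                f"centered rolling std (population) of {name} over round({w_s:g}*fps) frames, edge padded")

    df = pd.DataFrame(cols)
    if df.isna().any().any():
        raise FeatureError("internal error: NaN in feature matrix")
    version = _registry_version(reg, windows_s)
    return FeatureMatrix(df, reg, version, float(fps), tuple(windows_s))
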