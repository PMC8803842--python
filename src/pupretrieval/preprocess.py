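"""Tracking quality control and distance standardisation.

Pose-estimation output contains occasional impossible locations or
movements (a body part teleporting across the cage for one frame, or
drifting away from the animal). These are detected with two median-based
criteria derived from the nose-to-spine1 separation of each animal:

* movement outlier — a part whose displacement from its last accepted
  location exceeds ``median(nose, spine1 distance) * 2.5``;
* location outlier — a part farther than ``median * 4`` from at least two
  other body parts of the same animal.

Flagged coordinates are replaced by the part's last accepted (non-outlier)
location, a causal carry-forward that never looks ahead. The two passes are
iterated to a fixed point so that re-applying the correction is a no-op.

Pixel distances are standardised to millimetres using an in-frame landmark
pair of known physical length (the 265 mm span between the home-cage lid
hinges on a Type-II cage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .pose_io import PoseTrack


class PreprocessError(ValueError):
    pass


@dataclass
class OutlierCriteria:
    """Per-animal movement/location thresholds (same unit as the track)."""

    medians: Dict[str, float]
    movement_factor: float = 2.5
    location_factor: float = 4.0

    def __post_init__(self) -> None:
        for animal, m in self.medians.items():
            if not m > 0:
                raise PreprocessError(f"degenerate track: zero median nose-spine1 distance for {animal}")

    def movement(self, animal: str) -> float:
        return self.medians[animal] * self.movement_factor

    def location(self, animal: str) -> float:
        return self.medians[animal] * self.location_factor


@dataclass
class OutlierReport:
    """Correction counts per body part plus the criteria used."""

    movement_corrections: Dict[Tuple[str, str], int]
    location_corrections: Dict[Tuple[str, str], int]
    criteria: OutlierCriteria
    uncorrectable_frame0: list = field(default_factory=list)
    sweeps: int = 1

    @property
    def total_movement(self) -> int:
        return sum(self.movement_corrections.values())

    @property
    def total_location(self) -> int:
        return sum(self.location_corrections.values())

    @property
    def total(self) -> int:
        return self.total_movement + self.total_location

    def to_dict(self) -> dict:
        return {
            "movement_corrections": {f"{a}_{p}": n for (a, p), n in self.movement_corrections.items()},
            "location_corrections": {f"{a}_{p}": n for (a, p), n in self.location_corrections.items()},
            "movement_criterion": {a: self.criteria.movement(a) for a in self.criteria.medians},
            "location_criterion": {a: self.criteria.location(a) for a in self.criteria.medians},
            "movement_factor": self.criteria.movement_factor,
            "location_factor": self.criteria.location_factor,
            "uncorrectable_frame0": [f"{a}_{p}" for a, p in self.uncorrectable_frame0],
            "sweeps": self.sweeps,
        }


def compute_criteria(track: PoseTrack, movement_factor: float = 2.5,
                     location_factor: float = 4.0) -> OutlierCriteria:
    """Median nose-spine1 distance per animal, scaled by the two factors."""
    if movement_factor <= 0 or location_factor <= 0:
        raise PreprocessError("criterion factors must be positive")
    medians = {}
    animals = sorted({a for a, _ in track.body_parts})
    for animal in animals:
        try:
            nose = track.xy(animal, "nose")
            spine1 = track.xy(animal, "spine1")
        except KeyError:
            raise PreprocessError(f"animal {animal!r} lacks a 'nose' or 'spine1' part") from None
        d = np.linalg.norm(nose - spine1, axis=1)
        d = d[np.isfinite(d)]
        if d.size == 0:
            raise PreprocessError(f"all nose-spine1 distances missing for {animal!r}")
        medians[animal] = float(np.median(d))
    return OutlierCriteria(medians, movement_factor, location_factor)


def _movement_pass(coords: np.ndarray, crit: float) -> int:
    """Carry-forward correction of single-part jumps; mutates coords (frames, 2)."""
    n = 0
    last = coords[0].copy()
    for t in range(1, coords.shape[0]):
        if np.hypot(*(coords[t] - last)) > crit:
            coords[t] = last
            n += 1
        else:
            last = coords[t].copy()
    return n


def _location_pass(xy: np.ndarray, crit: float) -> np.ndarray:
    """Replace parts far from >= 2 same-animal parts; mutates xy (frames, k, 2).

    Returns per-part correction counts. Outlier status is evaluated on the
    incoming coordinates of each frame (not on values already replaced in
    the same sweep), keeping the pass order-independent within a frame.
    """
    frames, k, _ = xy.shape
    diff = xy[:, :, None, :] - xy[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (frames, k, k)
    far = (dist > crit).sum(axis=2)  # self-distance is 0, never counted
    outlier = far >= 2
    counts = np.zeros(k, dtype=int)
    last_good = xy[0].copy()
    for t in range(frames):
        for j in range(k):
            if outlier[t, j]:
                if t == 0:
                    continue  # no earlier accepted location; flagged by caller
                # a correction is an actual change; re-asserting an already
                # carried-forward value is not counted, so sweeps converge
                if not np.array_equal(xy[t, j], last_good[j]):
                    xy[t, j] = last_good[j]
                    counts[j] += 1
            else:
                last_good[j] = xy[t, j]
    return counts


def correct_outliers(track: PoseTrack, criteria: OutlierCriteria,
                     max_sweeps: int = 25) -> Tuple[PoseTrack, OutlierReport]:
    """Correct movement and location outliers by last-accepted carry-forward.

    Pass 1 replaces any part whose displacement from its last accepted
    location exceeds the movement criterion; pass 2 replaces any part
    farther than the location criterion from at least two other parts of
    the same animal. The pair of passes is repeated until no correction is
    made (a location replacement can re-expose a movement violation), so
    the returned track is a fixed point: a second call makes zero
    corrections. Frame 0 has no accepted predecessor; an outlier there is
    kept and flagged in the report. Likelihoods are untouched.
    """
    out = track.copy()
    mov = {bp: 0 for bp in track.body_parts}
    loc = {bp: 0 for bp in track.body_parts}
    animals = sorted({a for a, _ in track.body_parts})

    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        changed = 0
        for i, (animal, part) in enumerate(out.body_parts):
            n = _movement_pass(out.coords[:, i, :2], criteria.movement(animal))
            mov[(animal, part)] += n
            changed += n
        for animal in animals:
            idx = out.animal_indices(animal)
            xy = out.coords[:, idx, :2]
            counts = _location_pass(xy, criteria.location(animal))
            out.coords[:, idx, :2] = xy
            changed += int(counts.sum())
            for j, gi in enumerate(idx):
                loc[out.body_parts[gi]] += int(counts[j])
        if changed == 0:
            break

    frame0_flags = _frame0_outliers(out, criteria)
    report = OutlierReport(mov, loc, criteria, uncorrectable_frame0=frame0_flags, sweeps=sweeps)
    return out, report


def _frame0_outliers(track: PoseTrack, criteria: OutlierCriteria) -> list:
    flags = []
    animals = sorted({a for a, _ in track.body_parts})
    for animal in animals:
        idx = track.animal_indices(animal)
        xy0 = track.coords[0, idx, :2]
        dist = np.linalg.norm(xy0[:, None, :] - xy0[None, :, :], axis=-1)
        far = (dist > criteria.location(animal)).sum(axis=1)
        for j, gi in enumerate(idx):
            if far[j] >= 2:
                flags.append(track.body_parts[gi])
    return flags


@dataclass
class Calibration:
    """Pixel-to-millimetre scale from an in-frame landmark pair."""

    reference_px: float
    reference_mm: float = 265.0

    def __post_init__(self) -> None:
        if not self.reference_px > 0:
            raise PreprocessError("landmark separation must be positive")
        if not self.reference_mm > 0:
            raise PreprocessError("reference length must be positive")

    @property
    def scale(self) -> float:
        """Millimetres per pixel."""
        return self.reference_mm / self.reference_px


def calibrate(landmark_a, landmark_b, reference_mm: float = 265.0) -> Calibration:
    """Calibration from two pixel landmarks of known physical separation."""
    a = np.asarray(landmark_a, dtype=float)
    b = np.asarray(landmark_b, dtype=float)
    d = float(np.linalg.norm(a - b))
    if d <= 0:
        raise PreprocessError("calibration landmarks are coincident")
    return Calibration(reference_px=d, reference_mm=reference_mm)


def to_mm(track: PoseTrack, calibration: Calibration) -> PoseTrack:
    """Convert a pixel-unit track to millimetres. Likelihoods are unchanged."""
    if track.unit != "px":
        raise PreprocessError(f"track unit is {track.unit!r}, expected 'px' (no double scaling)")
    out = track.copy()
    out.coords[:, :, :2] *= calibration.scale
    out.unit = "mm"
    return out


def filter_low_likelihood(track: PoseTrack, floor: float = 0.2) -> PoseTrack:
    """Optional confidence floor: carry the last confident location forward.

    Off by default in the pipeline; the quality-control criteria above are
    purely distance based and do not consume likelihoods.
    """
    out = track.copy()
    for i in range(out.n_parts):
        lik = out.coords[:, i, 2]
        last = out.coords[0, i, :2].copy()
        for t in range(out.n_frames):
            if lik[t] < floor and t > 0:
                out.coords[t, i, :2] = last
            else:
                last = out.coords[t, i, :2].copy()
    return out
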