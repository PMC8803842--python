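"""Reading and writing pose tables, annotations, and trial metadata.

Pose tables use the DeepLabCut export dialect: a comma-separated file with
three header rows (``scorer``, ``bodyparts``, ``coords``) where every body
part contributes three columns (x, y, likelihood), followed by one row per
frame with a leading frame-index column.

The canonical pose configuration tracks 14 body parts, seven on the dam and
seven on the isolated pup: nose, ear_left, ear_right, spine1, spine2,
spine3, tail_base for each animal. ``nose`` and ``spine1`` must exist by
those names because the tracking quality-control criteria are defined from
their separation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

PART_NAMES = ("nose", "ear_left", "ear_right", "spine1", "spine2", "spine3", "tail_base")
ANIMALS = ("dam", "pup")

#: default body-part column names in a pose table (animal-prefixed)
DEFAULT_BODYPARTS = tuple(f"{a}_{p}" for a in ANIMALS for p in PART_NAMES)

_SCORER = "pupretrieval"


class PoseIOError(ValueError):
    """Raised for malformed pose tables, annotations or metadata files."""


@dataclass
class PoseTrack:
    """Per-frame (x, y, likelihood) coordinates for a set of named body parts.

    Parameters
    ----------
    coords
        Array of shape ``(frames, parts, 3)`` holding x, y, likelihood.
    body_parts
        Ordered list of ``(animal, part)`` tuples, one per parts axis entry.
    fps
        Recording frame rate in frames per second.
    unit
        Coordinate unit, ``"px"`` or ``"mm"``.
    """

    coords: np.ndarray
    body_parts: list
    fps: float
    unit: str = "px"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise PoseIOError("coords must have shape (frames, parts, 3)")
        if self.coords.shape[0] < 1:
            raise PoseIOError("no frames")
        if self.coords.shape[1] != len(self.body_parts):
            raise PoseIOError("body_parts length does not match coords")
        if self.unit not in ("px", "mm"):
            raise PoseIOError(f"unknown unit {self.unit!r}")
        if self.fps <= 0:
            raise PoseIOError("fps must be positive")
        lik = self.coords[:, :, 2]
        finite = lik[np.isfinite(lik)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise PoseIOError("likelihood values outside [0, 1]")
        self.body_parts = [tuple(bp) for bp in self.body_parts]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_parts(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def part_index(self, animal: str, part: str) -> int:
        try:
            return self.body_parts.index((animal, part))
        except ValueError:
            raise KeyError(f"body part ({animal!r}, {part!r}) not in track") from None

    def animal_indices(self, animal: str) -> np.ndarray:
        idx = np.array([i for i, (a, _) in enumerate(self.body_parts) if a == animal], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown animal {animal!r}")
        return idx

    def xy(self, animal: str, part: str) -> np.ndarray:
        """(frames, 2) x/y view of one body part."""
        return self.coords[:, self.part_index(animal, part), :2]

    def likelihood(self, animal: str, part: str) -> np.ndarray:
        return self.coords[:, self.part_index(animal, part), 2]

    def copy(self) -> "PoseTrack":
        return PoseTrack(self.coords.copy(), list(self.body_parts), self.fps, self.unit)


@dataclass
class AnnotationTrack:
    """Per-frame binary presence/absence annotation for one behavior."""

    behavior: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise PoseIOError(
                f"annotation {self.behavior!r} has value {self.values[row]} at row {row}; "
                "expected 0 or 1"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class TrialMeta:
    """Trial-level metadata: identity, frame rate, trial cap, calibration.

    ``max_trial_s`` is the maximum trial duration; failed retrievals are
    assigned this value as their retrieval time. ``calibration_reference_mm``
    is the physical length of the in-frame landmark pair (the span between
    the home-cage lid hinges, 265 mm on a Type-II cage) used to convert
    pixels to millimetres; ``calibration_px`` holds the two landmark pixel
    coordinates when known.
    """

    trial_id: str
    fps: float
    max_trial_s: float = 90.0
    calibration_reference_mm: float = 265.0
    calibration_px: Optional[list] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise PoseIOError("fps must be positive")
        if self.max_trial_s <= 0:
            raise PoseIOError("max_trial_s must be positive")
        if self.calibration_px is not None:
            pts = np.asarray(self.calibration_px, dtype=float)
            if pts.shape != (2, 2):
                raise PoseIOError("calibration_px must be two (x, y) points")
            self.calibration_px = pts.tolist()

    def to_dict(self) -> dict:
        d = {
            "trial_id": self.trial_id,
            "fps": self.fps,
            "max_trial_s": self.max_trial_s,
            "calibration_reference_mm": self.calibration_reference_mm,
        }
        if self.calibration_px is not None:
            d["calibration_px"] = self.calibration_px
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialMeta":
        return cls(
            trial_id=str(d["trial_id"]),
            fps=float(d["fps"]),
            max_trial_s=float(d.get("max_trial_s", 90.0)),
            calibration_reference_mm=float(d.get("calibration_reference_mm", 265.0)),
            calibration_px=d.get("calibration_px"),
        )


def _split_name(name: str, animal_map: Optional[Mapping[str, str]]):
    """Resolve a pose-table body-part column name to (animal, part)."""
    if animal_map is not None and name in animal_map:
        animal = animal_map[name]
        part = name[len(animal) + 1:] if name.startswith(animal + "_") else name
        return animal, part
    for animal in ANIMALS:
        if name.startswith(animal + "_"):
            return animal, name[len(animal) + 1:]
    raise PoseIOError(
        f"cannot assign body part {name!r} to an animal; "
        "prefix it with 'dam_'/'pup_' or supply animal_map"
    )


def read_pose_table(path, fps: float, animal_map: Optional[Mapping[str, str]] = None) -> PoseTrack:
    """Read a DeepLabCut-dialect pose table.

    Parameters
    ----------
    path
        CSV file with three header rows (scorer / bodyparts / coords).
    fps
        Frame rate of the recording; the dialect does not carry it.
    animal_map
        Optional mapping from body-part column name to animal name. When
        given, the default requirement of exactly 14 canonical parts (7 dam
        + 7 pup) is lifted.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise PoseIOError(f"{path}: expected 3 header rows, found {len(rows)} rows")
    scorer_row, bp_row, coords_row = rows[0], rows[1], rows[2]
    if not scorer_row or scorer_row[0] != "scorer":
        raise PoseIOError(f"{path}: header row 1 must start with 'scorer'")
    if not bp_row or bp_row[0] != "bodyparts":
        raise PoseIOError(f"{path}: header row 2 must start with 'bodyparts'")
    if not coords_row or coords_row[0] != "coords":
        raise PoseIOError(f"{path}: header row 3 must start with 'coords'")
    ncol = len(bp_row)
    if len(coords_row) != ncol or (ncol - 1) % 3 != 0 or ncol < 4:
        raise PoseIOError(f"{path}: header row 3 does not pair x,y,likelihood per body part")

    names = []
    for j in range(1, ncol, 3):
        trip = bp_row[j:j + 3]
        if len(set(trip)) != 1:
            raise PoseIOError(f"{path}: header row 2 body-part names not in triplets near column {j}")
        if coords_row[j:j + 3] != ["x", "y", "likelihood"]:
            raise PoseIOError(
                f"{path}: header row 3 must read x,y,likelihood for part {trip[0]!r}"
            )
        names.append(trip[0])

    if animal_map is None and len(names) != 14:
        raise PoseIOError(
            f"{path}: expected 14 body parts (7 dam + 7 pup), found {len(names)}; "
            "pass animal_map to override"
        )
    body_parts = [_split_name(n, animal_map) for n in names]

    data_rows = rows[3:]
    data_rows = [r for r in data_rows if any(c.strip() for c in r)]
    if not data_rows:
        raise PoseIOError(f"{path}: no frames")
    coords = np.empty((len(data_rows), len(names), 3), dtype=float)
    for i, row in enumerate(data_rows):
        if len(row) != ncol:
            raise PoseIOError(f"{path}: frame {i} has {len(row)} columns, expected {ncol}")
        try:
            vals = [float(v) for v in row[1:]]
        except ValueError:
            bad = next(v for v in row[1:] if not _is_number(v))
            raise PoseIOError(f"{path}: non-numeric cell {bad!r} at frame {i}") from None
        coords[i] = np.asarray(vals).reshape(len(names), 3)

    # unit survives round-trips via a suffix on the scorer name
    unit = "mm" if any(c.endswith(":mm") for c in scorer_row[1:]) else "px"
    return PoseTrack(coords, body_parts, fps=fps, unit=unit)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_pose_table(track: PoseTrack, path) -> None:
    """Write a PoseTrack in the DeepLabCut dialect readable by read_pose_table."""
    path = Path(path)
    names = [f"{a}_{p}" for a, p in track.body_parts]
    scorer = f"{_SCORER}:{track.unit}"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * len(names)))
        w.writerow(["bodyparts"] + [n for n in names for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(names))
        flat = track.coords.reshape(track.n_frames, -1)
        for i in range(track.n_frames):
            w.writerow([i] + [repr(float(v)) for v in flat[i]])


def read_annotations(path, n_frames: int) -> dict:
    """Read frame-level binary behavior annotations.

    One column per behavior (header row of behavior names), one row per
    frame. Returns an ordered ``{behavior: AnnotationTrack}`` dict.
    """
    df = pd.read_csv(path)
    if len(df) != n_frames:
        raise PoseIOError(
            f"{path}: annotation length {len(df)} does not match track frames {n_frames}"
        )
    out = {}
    for col in df.columns:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise PoseIOError(f"{path}: value {vals[row]!r} at row {row} of {col!r}; expected 0/1")
        out[str(col)] = AnnotationTrack(str(col), vals.astype(np.int8))
    return out


def write_annotations(tracks: Mapping[str, AnnotationTrack] | Mapping[str, Sequence[int]], path) -> None:
    cols = {}
    for name, t in tracks.items():
        vals = t.values if isinstance(t, AnnotationTrack) else np.asarray(t, dtype=np.int8)
        cols[name] = vals
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trial_meta(path) -> TrialMeta:
    """Read trial metadata from a YAML or JSON file."""
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise PoseIOError(f"{path}: expected a mapping")
    try:
        return TrialMeta.from_dict(d)
    except KeyError as e:
        raise PoseIOError(f"{path}: missing required field {e}") from None


def write_trial_meta(meta: TrialMeta, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(meta.to_dict(), fh, indent=2)
        else:
            yaml.safe_dump(meta.to_dict(), fh, sort_keys=False)
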