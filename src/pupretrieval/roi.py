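"""Nest regions of interest and per-frame occupancy.

Two fixed ROIs are defined per trial video: the *nest*, a simple polygon
enclosing the whole nesting site, and the *core nest*, a circle enclosing
only the part of the nest holding the pups. Spatial events (a pup entering
the nest, the dam digging near the core) are defined from per-frame body
part membership in these regions.

Boundary convention: points on an ROI boundary count as inside, for both
shapes. Nest edges are exactly where scoring disagreements concentrate, so
the convention is explicit and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .pose_io import PoseIOError, PoseTrack


class ROIError(ValueError):
    pass


@dataclass
class Circle:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not self.radius > 0:
            raise ROIError("circle radius must be positive")


@dataclass
class ROIConfig:
    """Nest polygon plus core-nest circle, in pixel (or jointly scaled) coordinates."""

    nest: np.ndarray
    core_nest: Circle
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.nest = np.asarray(self.nest, dtype=float)
        if self.nest.ndim != 2 or self.nest.shape[1] != 2 or self.nest.shape[0] < 3:
            raise ROIError("nest polygon needs >= 3 (x, y) vertices")
        poly = Polygon(self.nest)
        if not poly.is_valid or poly.area <= 0:
            raise ROIError("nest polygon must be simple (non-self-intersecting) with positive area")
        if isinstance(self.core_nest, dict):
            self.core_nest = Circle(**self.core_nest)

    @property
    def nest_polygon(self) -> Polygon:
        return Polygon(self.nest)

    @property
    def nest_center(self) -> np.ndarray:
        c = self.nest_polygon.centroid
        return np.array([c.x, c.y])

    def scaled(self, factor: float) -> "ROIConfig":
        """ROI with all coordinates multiplied by ``factor`` (e.g. mm per px)."""
        return ROIConfig(
            nest=self.nest * factor,
            core_nest=Circle(self.core_nest.center * factor, self.core_nest.radius * factor),
            trial_id=self.trial_id,
        )

    def translated(self, dx: float, dy: float) -> "ROIConfig":
        shift = np.array([dx, dy], dtype=float)
        return ROIConfig(
            nest=self.nest + shift,
            core_nest=Circle(self.core_nest.center + shift, self.core_nest.radius),
            trial_id=self.trial_id,
        )

    def to_dict(self) -> dict:
        d = {
            "nest": [[float(x), float(y)] for x, y in self.nest],
            "core_nest": {
                "center": [float(self.core_nest.center[0]), float(self.core_nest.center[1])],
                "radius": float(self.core_nest.radius),
            },
        }
        if self.trial_id is not None:
            d["trial_id"] = self.trial_id
        return d

    @classmethod
    def from_dict(cls, d) -> "ROIConfig":
        core = d["core_nest"]
        return cls(
            nest=np.asarray(d["nest"], dtype=float),
            core_nest=Circle(np.asarray(core["center"], dtype=float), float(core["radius"])),
            trial_id=d.get("trial_id"),
        )


def read_roi_config(path) -> ROIConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "nest" not in d or "core_nest" not in d:
        raise ROIError(f"{path}: expected mapping with 'nest' and 'core_nest'")
    return ROIConfig.from_dict(d)


def write_roi_config(roi: ROIConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(roi.to_dict(), fh, sort_keys=False)


def point_in_polygon(point, polygon) -> bool:
    """True iff the point is inside the polygon or on its boundary."""
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ROIError("degenerate polygon")
    x, y = float(point[0]), float(point[1])
    return bool(shapely.intersects_xy(poly, x, y))


def points_in_polygon(points: np.ndarray, polygon) -> np.ndarray:
    """Vectorised boundary-inclusive membership test for an (n, 2) array."""
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ROIError("degenerate polygon")
    pts = np.asarray(points, dtype=float)
    return shapely.intersects_xy(poly, pts[..., 0], pts[..., 1])


def point_in_circle(point, circle: Circle) -> bool:
    """True iff distance(point, center) <= radius (boundary inside)."""
    p = np.asarray(point, dtype=float)
    return bool(np.hypot(*(p - circle.center)) <= circle.radius)


def points_in_circle(points: np.ndarray, circle: Circle) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts - circle.center, axis=-1)
    return d <= circle.radius


def roi_occupancy(track: PoseTrack, roi: ROIConfig, animal: str,
                  mode: str = "any", region: str = "nest") -> np.ndarray:
    """Per-frame boolean occupancy of an ROI region by one animal.

    mode="any": a frame is occupied when at least one of the animal's body
    parts is inside the region; mode="all": every part must be inside.
    Track and ROI must be in the same unit and coordinate frame.
    """
    if mode not in ("any", "all"):
        raise ROIError(f"unknown mode {mode!r}")
    idx = track.animal_indices(animal)  # raises KeyError for unknown animal
    pts = track.coords[:, idx, :2]  # (frames, k, 2)
    flat = pts.reshape(-1, 2)
    if region == "nest":
        inside = points_in_polygon(flat, roi.nest_polygon)
    elif region == "core_nest":
        inside = points_in_circle(flat, roi.core_nest)
    else:
        raise ROIError(f"unknown region {region!r}")
    inside = inside.reshape(pts.shape[0], pts.shape[1])
    return inside.any(axis=1) if mode == "any" else inside.all(axis=1)
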