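"""Synthetic dam+pup retrieval trials with known ground truth.

Every pipeline stage — table I/O, outlier correction, calibration, ROI
occupancy, feature extraction, classifier training, retrieval scoring —
is testable against trials generated here, without any recorded video.
A :class:`Scenario` scripts a trial as ordered behavioral episodes on the
default recording geometry (1280x720 px overhead view of a Type-II cage,
lid-hinge landmarks 530 px apart for the 265 mm calibration, nest polygon
and core-nest circle in one corner):

* ``idle`` — both animals wander in place (small Gaussian steps);
* ``approach`` — the dam travels toward the near-stationary pup and the
  frames where she is actually closing distance carry the approach label;
* ``carry`` / ``retrieve`` — the dam's nose stays within the coupling
  distance of the pup centroid while both translate toward the core nest;
  a ``retrieve`` episode is scripted to end with the pup inside the nest;
* ``dig`` — the dam holds near the nest with oscillatory body-part motion;
* ``nest_shift`` — the pup translates into the nest with no carry label,
  emulating the failure mode where a moved nest (or wandering pup) puts
  pup parts inside a stale ROI without a retrieval.

Kinematics are minimal-but-sufficient: rigid body templates (seven parts
per animal) follow a smooth centroid/heading state with per-part Gaussian
jitter. Realistic tracking faults are layered on separately by
:func:`inject_tracking_noise` (single-frame teleports scaled to the
movement outlier criterion, and likelihood drops emulating occlusion),
with every injection recorded so correction can be audited.

Ground truth is script-intent based: a trial is retrieved only when the
pup's nest entry happens during a scripted ``retrieve`` episode, so the
retrieval scoring rule is checked against an independent notion of truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from shapely.geometry import LineString, Polygon

from .pose_io import ANIMALS, PART_NAMES, PoseTrack, TrialMeta, write_annotations, write_pose_table, write_trial_meta
from .preprocess import compute_criteria
from .roi import Circle, ROIConfig, roi_occupancy, write_roi_config

BEHAVIOR_LABELS = ("approach", "carry", "digging")
EPISODE_KINDS = ("idle", "approach", "carry", "dig", "retrieve", "nest_shift")

# rigid body templates: part offsets from the centroid, heading along +x (px)
DAM_TEMPLATE = np.array(
    [[34.0, 0.0], [22.0, -11.0], [22.0, 11.0], [14.0, 0.0],
     [0.0, 0.0], [-14.0, 0.0], [-30.0, 0.0]])
PUP_SCALE = 0.6
PUP_TEMPLATE = DAM_TEMPLATE * PUP_SCALE

# default recording geometry (px)
CAGE_PX = (1280.0, 720.0)
NEST_PX = ((120.0, 470.0), (350.0, 470.0), (350.0, 690.0), (120.0, 690.0))
CORE_CENTER_PX = (235.0, 580.0)
CORE_RADIUS_PX = 45.0
DAM_START_PX = (235.0, 580.0)
PUP_START_PX = (1080.0, 110.0)
CALIBRATION_PX = ((375.0, 40.0), (905.0, 40.0))  # 530 px -> 265 mm -> 2 px/mm


class ScenarioError(ValueError):
    pass


@dataclass
class Episode:
    """One scripted behavioral episode with its kinematic parameters."""

    behavior: str
    start_s: float
    end_s: float
    speed_mm_s: float = 60.0
    coupling_mm: float = 10.0
    dig_amplitude_mm: float = 4.0
    dig_frequency_hz: float = 2.0

    def __post_init__(self) -> None:
        if self.behavior not in EPISODE_KINDS:
            raise ScenarioError(f"unknown episode behavior {self.behavior!r}")
        if not 0 <= self.start_s < self.end_s:
            raise ScenarioError(f"bad episode times ({self.start_s}, {self.end_s})")


@dataclass
class NoiseSpec:
    """Tracking imperfection model: jitter, one-frame jumps, occlusions."""

    jitter_px: float = 1.0
    jump_rate: float = 0.005
    jump_magnitude_factor: float = 5.0
    occlusion_rate: float = 0.01

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(jitter_px=0.0, jump_rate=0.0, occlusion_rate=0.0)

    @classmethod
    def jitter_only(cls, sigma_px: float = 1.0) -> "NoiseSpec":
        return cls(jitter_px=sigma_px, jump_rate=0.0, occlusion_rate=0.0)


@dataclass
class Scenario:
    """Full specification of one synthetic trial."""

    episodes: List[Episode]
    fps: float = 10.0
    trial_s: float = 90.0
    seed: int = 0
    trial_id: str = "synthetic"
    cage_px: Tuple[float, float] = CAGE_PX
    nest_px: Tuple = NEST_PX
    core_center_px: Tuple[float, float] = CORE_CENTER_PX
    core_radius_px: float = CORE_RADIUS_PX
    dam_start_px: Tuple[float, float] = DAM_START_PX
    pup_start_px: Tuple[float, float] = PUP_START_PX
    calibration_px: Tuple = CALIBRATION_PX
    calibration_mm: float = 265.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    idle_sigma_px: float = 0.8  # dam wander step during idle
    pup_idle_sigma_px: float = 0.15

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.trial_s <= 0:
            raise ScenarioError("fps and trial_s must be positive")
        eps = sorted(self.episodes, key=lambda e: e.start_s)
        for e in eps:
            if e.end_s > self.trial_s + 1e-9:
                raise ScenarioError(f"episode {e.behavior} ends after the trial")
        for e1, e2 in zip(eps, eps[1:]):
            if e2.start_s < e1.end_s - 1e-9:
                raise ScenarioError(
                    f"episodes overlap: {e1.behavior} and {e2.behavior}")
        carriers = [e for e in eps if e.behavior in ("carry", "retrieve")]
        for e in carriers:
            if not any(a.behavior == "approach" and a.end_s <= e.start_s + 1e-9 for a in eps):
                warnings.warn(
                    f"{e.behavior} episode at {e.start_s:.1f}s has no prior approach; "
                    "the dam will travel to the pup unlabeled", stacklevel=2)
        self.episodes = eps

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_s * self.fps))

    @property
    def px_per_mm(self) -> float:
        a, b = np.asarray(self.calibration_px, dtype=float)
        return float(np.linalg.norm(a - b) / self.calibration_mm)

    def roi(self) -> ROIConfig:
        return ROIConfig(np.asarray(self.nest_px, dtype=float),
                         Circle(np.asarray(self.core_center_px, dtype=float),
                                self.core_radius_px),
                         trial_id=self.trial_id)

    def meta(self) -> TrialMeta:
        return TrialMeta(trial_id=self.trial_id, fps=self.fps, max_trial_s=self.trial_s,
                         calibration_reference_mm=self.calibration_mm,
                         calibration_px=[list(p) for p in np.asarray(self.calibration_px, float)])

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id, "fps": self.fps, "trial_s": self.trial_s,
            "seed": self.seed,
            "episodes": [
                {"behavior": e.behavior, "start_s": e.start_s, "end_s": e.end_s,
                 "speed_mm_s": e.speed_mm_s, "coupling_mm": e.coupling_mm,
                 "dig_amplitude_mm": e.dig_amplitude_mm,
                 "dig_frequency_hz": e.dig_frequency_hz}
                for e in self.episodes],
            "noise": {"jitter_px": self.noise.jitter_px, "jump_rate": self.noise.jump_rate,
                      "jump_magnitude_factor": self.noise.jump_magnitude_factor,
                      "occlusion_rate": self.noise.occlusion_rate},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        episodes = [Episode(**e) for e in d.get("episodes", [])]
        noise = NoiseSpec(**d["noise"]) if "noise" in d else NoiseSpec()
        kwargs = {k: d[k] for k in ("fps", "trial_s", "seed", "trial_id") if k in d}
        return cls(episodes=episodes, noise=noise, **kwargs)


@dataclass
class OutlierInjection:
    frame: int
    part_index: int
    true_xy: Tuple[float, float]


@dataclass
class GroundTruth:
    """Frame-accurate labels and the script-intent retrieval outcome."""

    labels: Dict[str, np.ndarray]
    retrieved: int
    retrieval_frame: Optional[int]
    pup_in_nest: np.ndarray
    outliers: List[OutlierInjection] = field(default_factory=list)


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _turn_toward(heading: float, target: float, max_step: float) -> float:
    d = (target - heading + math.pi) % (2 * math.pi) - math.pi
    return heading + np.clip(d, -max_step, max_step)


def generate_trial(scenario: Scenario):
    """Simulate one trial.

    Returns ``(PoseTrack, GroundTruth, ROIConfig, TrialMeta)``. The track is
    bit-reproducible for a given scenario (including its seed); ground-truth
    occupancy and retrieval are computed on the clean coordinates before any
    jump/occlusion injection.
    """
    rng = np.random.default_rng(scenario.seed)
    fps = scenario.fps
    n = scenario.n_frames
    ppm = scenario.px_per_mm
    max_turn = 3.5 / fps  # rad per frame; keeps nose sweep below the jump criterion

    schedule: List[Optional[Episode]] = [None] * n
    for e in scenario.episodes:
        f0, f1 = int(round(e.start_s * fps)), min(n, int(round(e.end_s * fps)))
        for t in range(f0, f1):
            schedule[t] = e

    core = np.asarray(scenario.core_center_px, dtype=float)
    dig_anchor = core + np.array([scenario.core_radius_px + 35.0, 0.0])

    dam_pos = np.asarray(scenario.dam_start_px, dtype=float).copy()
    pup_pos = np.asarray(scenario.pup_start_px, dtype=float).copy()
    dam_heading = 0.0
    pup_heading = math.pi
    nose_off = DAM_TEMPLATE[0]

    dam_states = np.empty((n, 3))
    pup_states = np.empty((n, 3))
    dig_active = np.zeros(n, dtype=bool)
    labels = {b: np.zeros(n, dtype=np.int8) for b in BEHAVIOR_LABELS}

    idle_sigma = scenario.idle_sigma_px
    pup_idle_sigma = scenario.pup_idle_sigma_px
    current_ep = None
    arrived = False  # per-episode latch: once a target is reached, stay there

    for t in range(n):
        ep = schedule[t]
        if ep is not current_ep:
            current_ep = ep
            arrived = False
        beh = ep.behavior if ep is not None else "idle"
        step_px = (ep.speed_mm_s * ppm / fps) if ep is not None else 0.0
        coupling_px = (ep.coupling_mm * ppm) if ep is not None else 20.0

        if beh in ("approach", "carry", "retrieve"):
            nose = dam_pos + _rot(dam_heading) @ nose_off
            gap = float(np.linalg.norm(pup_pos - nose))

        if beh == "idle":
            dam_pos = dam_pos + rng.normal(0.0, idle_sigma, 2)
            pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
        elif beh == "approach":
            contact = 0.8 * coupling_px
            if gap <= contact + 0.5:
                arrived = True
            if not arrived:
                direction = (pup_pos - nose) / gap
                dam_heading = _turn_toward(dam_heading, math.atan2(direction[1], direction[0]), max_turn)
                dam_pos = dam_pos + direction * min(step_px, gap - contact)
                labels["approach"][t] = 1
            else:
                dam_pos = dam_pos + rng.normal(0.0, pup_idle_sigma, 2)
            pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
        elif beh in ("carry", "retrieve"):
            if not arrived and gap > coupling_px:
                # script gap: walk to the pup first, unlabeled
                direction = (pup_pos - nose) / gap
                dam_heading = _turn_toward(dam_heading, math.atan2(direction[1], direction[0]), max_turn)
                dam_pos = dam_pos + direction * min(step_px, gap - 0.8 * coupling_px)
                pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
            else:
                to_core = core - pup_pos
                dist = float(np.linalg.norm(to_core))
                if dist <= 3.0:
                    arrived = True
                if not arrived:
                    direction = to_core / dist
                    target_heading = math.atan2(direction[1], direction[0])
                    pup_heading = _turn_toward(pup_heading, target_heading, max_turn)
                    dam_heading = _turn_toward(dam_heading, target_heading, max_turn)
                    pup_pos = pup_pos + direction * min(step_px, dist)
                    dam_pos = pup_pos - _rot(dam_heading) @ nose_off  # nose rides on the pup
                    labels["carry"][t] = 1
                else:
                    dam_pos = dam_pos + rng.normal(0.0, pup_idle_sigma, 2)
                    pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
        elif beh == "dig":
            to_anchor = dig_anchor - dam_pos
            dist = float(np.linalg.norm(to_anchor))
            if dist > 25.0:
                direction = to_anchor / dist
                dam_heading = _turn_toward(dam_heading, math.atan2(direction[1], direction[0]), max_turn)
                dam_pos = dam_pos + direction * min(step_px, dist)
            else:
                dam_pos = dam_pos + 0.1 * to_anchor + rng.normal(0.0, 1.2, 2)
                labels["digging"][t] = 1
                dig_active[t] = True
            pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
        elif beh == "nest_shift":
            to_core = core - pup_pos
            dist = float(np.linalg.norm(to_core))
            if dist > 3.0:
                direction = to_core / dist
                pup_heading = _turn_toward(pup_heading, math.atan2(direction[1], direction[0]), max_turn)
                pup_pos = pup_pos + direction * min(step_px, dist)
            else:
                pup_pos = pup_pos + rng.normal(0.0, pup_idle_sigma, 2)
            dam_pos = dam_pos + rng.normal(0.0, idle_sigma, 2)

        dam_pos = np.clip(dam_pos, (40.0, 40.0), np.asarray(scenario.cage_px) - 40.0)
        pup_pos = np.clip(pup_pos, (20.0, 20.0), np.asarray(scenario.cage_px) - 20.0)
        dam_states[t] = (dam_pos[0], dam_pos[1], dam_heading)
        pup_states[t] = (pup_pos[0], pup_pos[1], pup_heading)

    # place body parts from the rigid templates
    body_parts = [(a, p) for a in ANIMALS for p in PART_NAMES]
    coords = np.empty((n, 14, 3))
    dig_ep = next((e for e in scenario.episodes if e.behavior == "dig"), None)
    amp_px = (dig_ep.dig_amplitude_mm * ppm) if dig_ep is not None else 0.0
    freq = dig_ep.dig_frequency_hz if dig_ep is not None else 2.0
    dig_phase = rng.uniform(0, 2 * math.pi, 7)
    dig_dir = rng.normal(size=(7, 2))
    dig_dir /= np.linalg.norm(dig_dir, axis=1, keepdims=True)

    tt = np.arange(n) / fps
    for t in range(n):
        rd = _rot(dam_states[t, 2])
        dam_parts = dam_states[t, :2] + DAM_TEMPLATE @ rd.T
        if dig_active[t]:
            osc = amp_px * np.sin(2 * math.pi * freq * tt[t] + dig_phase)[:, None] * dig_dir
            dam_parts = dam_parts + osc
        rp = _rot(pup_states[t, 2])
        pup_parts = pup_states[t, :2] + PUP_TEMPLATE @ rp.T
        coords[t, :7, :2] = dam_parts
        coords[t, 7:, :2] = pup_parts

    if scenario.noise.jitter_px > 0:
        coords[:, :, :2] += rng.normal(0.0, scenario.noise.jitter_px, (n, 14, 2))
    coords[:, :, 2] = rng.uniform(0.9, 1.0, (n, 14))

    track = PoseTrack(coords, body_parts, fps=fps, unit="px")
    roi_cfg = scenario.roi()

    pup_in_nest = roi_occupancy(track, roi_cfg, "pup", "any", "nest")
    retrieved, retrieval_frame = _script_retrieval(scenario, pup_in_nest)

    outliers: List[OutlierInjection] = []
    if scenario.noise.jump_rate > 0 or scenario.noise.occlusion_rate > 0:
        track, outliers = inject_tracking_noise(
            track, scenario.noise.jump_rate, scenario.noise.jump_magnitude_factor,
            scenario.noise.occlusion_rate,
            seed=int(rng.integers(0, 2**31 - 1)))

    truth = GroundTruth(labels=labels, retrieved=retrieved,
                        retrieval_frame=retrieval_frame,
                        pup_in_nest=pup_in_nest, outliers=outliers)
    return track, truth, roi_cfg, scenario.meta()


def _script_retrieval(scenario: Scenario, pup_in_nest: np.ndarray):
    """Script-intent truth: retrieved iff the nest entry falls in a retrieve episode."""
    entries = np.flatnonzero(pup_in_nest & ~np.concatenate([[False], pup_in_nest[:-1]]))
    if entries.size == 0:
        return 0, None
    first = int(entries[0])
    fps = scenario.fps
    for e in scenario.episodes:
        if e.behavior == "retrieve":
            f0 = int(round(e.start_s * fps))
            f1 = int(round(e.end_s * fps)) + 2  # rounding slack at the episode edge
            if f0 <= first <= f1:
                return 1, first
    return 0, None


def inject_tracking_noise(track: PoseTrack, jump_rate: float,
                          jump_magnitude_factor: float = 5.0,
                          occlusion_rate: float = 0.0, seed: int = 0):
    """Layer tracking faults onto a clean track.

    Each part-frame is independently teleported with probability
    ``jump_rate`` by ``jump_magnitude_factor`` times that animal's movement
    outlier criterion, in a uniformly random direction, for a single frame;
    with probability ``occlusion_rate`` its likelihood is redrawn below
    0.2. Every jump is recorded with the true location it displaced.
    """
    for r in (jump_rate, occlusion_rate):
        if not 0 <= r <= 1:
            raise ScenarioError("noise rates must lie in [0, 1]")
    out = track.copy()
    registry: List[OutlierInjection] = []
    rng = np.random.default_rng(seed)

    if jump_rate > 0:
        criteria = compute_criteria(track)
        mags = np.array([jump_magnitude_factor * criteria.movement(a)
                         for a, _ in track.body_parts])
        mask = rng.random((track.n_frames, track.n_parts)) < jump_rate
        # frame 0 anchors the carry-forward correction ("frame 0 is always
        # accepted"), so a frame-0 jump is uncorrectable by construction and
        # would freeze the whole part track; faults start at frame 1
        mask[0, :] = False
        angles = rng.uniform(0, 2 * math.pi, mask.shape)
        for t, j in zip(*np.nonzero(mask)):
            true_xy = out.coords[t, j, :2].copy()
            out.coords[t, j, 0] += mags[j] * math.cos(angles[t, j])
            out.coords[t, j, 1] += mags[j] * math.sin(angles[t, j])
            registry.append(OutlierInjection(int(t), int(j), (float(true_xy[0]), float(true_xy[1]))))

    if occlusion_rate > 0:
        occ_mask = rng.random((track.n_frames, track.n_parts)) < occlusion_rate
        out.coords[:, :, 2] = np.where(
            occ_mask, rng.uniform(0.0, 0.2, occ_mask.shape), out.coords[:, :, 2])

    return out, registry


# ---------------------------------------------------------------------------
# scenario factories

def _nest_path_cross_px(scenario_pup_start, core_center, nest_px) -> float:
    """Distance from the pup start to the nest boundary along the carry path."""
    line = LineString([tuple(scenario_pup_start), tuple(core_center)])
    hit = line.intersection(Polygon(np.asarray(nest_px, float)).exterior)
    if hit.is_empty:
        raise ScenarioError("carry path never crosses the nest boundary")
    return float(line.project(hit if hit.geom_type == "Point" else list(hit.geoms)[0]))


def retrieval_scenario(seed: int, fps: float = 10.0, entry_s: Optional[float] = None,
                       noise: Optional[NoiseSpec] = None, with_dig: bool = True,
                       trial_s: float = 90.0) -> Scenario:
    """A successful-retrieval script: idle, approach, retrieve, optional dig.

    When ``entry_s`` is given, the carry start is back-computed so the pup
    crosses the nest boundary at approximately that time.
    """
    rng = np.random.default_rng(seed)
    approach_speed = float(rng.uniform(50.0, 70.0))
    # carried-pup speed stays below half the pup movement criterion per frame
    # (criterion 30 px at 10 fps), so a corrected tracking jump re-converges
    # on the next frame instead of freezing the carry-forward state
    carry_speed = float(rng.uniform(45.0, 55.0))
    ppm = 2.0  # default geometry
    travel_px = float(np.linalg.norm(np.asarray(PUP_START_PX) - np.asarray(DAM_START_PX)))
    approach_dur = travel_px / (approach_speed * ppm) + 1.5
    cross_px = _nest_path_cross_px(PUP_START_PX, CORE_CENTER_PX, NEST_PX)
    cross_px -= PUP_TEMPLATE[0, 0]  # the pup nose leads the centroid on the path
    cross_dur = cross_px / (carry_speed * ppm)
    carry_total_px = float(np.linalg.norm(np.asarray(PUP_START_PX) - np.asarray(CORE_CENTER_PX)))
    carry_dur = carry_total_px / (carry_speed * ppm) + 1.0

    if entry_s is not None:
        c0 = entry_s - cross_dur
    else:
        c0 = float(rng.uniform(3.0, 8.0)) + approach_dur
    a0 = c0 - approach_dur
    if a0 < 0:
        raise ScenarioError("entry_s too early for the approach to complete")
    episodes = [
        Episode("approach", a0, c0, speed_mm_s=approach_speed),
        Episode("retrieve", c0, c0 + carry_dur, speed_mm_s=carry_speed),
    ]
    if with_dig:
        d0 = c0 + carry_dur + 2.0
        d1 = min(trial_s - 1.0, d0 + float(rng.uniform(11.0, 16.0)))
        if d1 > d0 + 2.0:
            episodes.append(Episode("dig", d0, d1, speed_mm_s=60.0))
    return Scenario(episodes, fps=fps, trial_s=trial_s, seed=seed,
                    trial_id=f"retrieve_{seed}",
                    noise=noise if noise is not None else NoiseSpec())


def no_retrieval_scenario(seed: int, fps: float = 10.0,
                          noise: Optional[NoiseSpec] = None,
                          with_dig: bool = True, trial_s: float = 90.0) -> Scenario:
    """A failure script: the dam approaches and digs but never carries."""
    rng = np.random.default_rng(seed)
    a0 = float(rng.uniform(3.0, 8.0))
    episodes = [Episode("approach", a0, a0 + 9.5, speed_mm_s=float(rng.uniform(50.0, 70.0)))]
    if with_dig:
        d0 = a0 + 9.5 + float(rng.uniform(2.0, 5.0))
        episodes.append(Episode("dig", d0, d0 + float(rng.uniform(11.0, 16.0)), speed_mm_s=60.0))
    return Scenario(episodes, fps=fps, trial_s=trial_s, seed=seed,
                    trial_id=f"fail_{seed}",
                    noise=noise if noise is not None else NoiseSpec())


def nest_shift_scenario(seed: int, fps: float = 10.0,
                        noise: Optional[NoiseSpec] = None,
                        trial_s: float = 90.0) -> Scenario:
    """Pup parts end up inside the nest ROI with no carry: must score 0."""
    rng = np.random.default_rng(seed)
    s0 = float(rng.uniform(8.0, 18.0))
    episodes = [Episode("nest_shift", s0, min(trial_s - 1.0, s0 + 22.0), speed_mm_s=30.0)]
    return Scenario(episodes, fps=fps, trial_s=trial_s, seed=seed,
                    trial_id=f"shift_{seed}",
                    noise=noise if noise is not None else NoiseSpec())


def idle_scenario(seed: int, fps: float = 10.0, trial_s: float = 90.0,
                  noise: Optional[NoiseSpec] = None) -> Scenario:
    """Both animals wander in place for the whole trial."""
    return Scenario([], fps=fps, trial_s=trial_s, seed=seed, trial_id=f"idle_{seed}",
                    noise=noise if noise is not None else NoiseSpec())


def stationary_scenario(seed: int, fps: float = 10.0, trial_s: float = 90.0,
                        noise: Optional[NoiseSpec] = None) -> Scenario:
    """Near-stationary animals: isolates the outlier-correction mechanism.

    Carry-forward correction restores a jumped part to the previous frame's
    location, so sub-pixel recovery is a property of the mechanism only when
    the underlying motion is itself sub-pixel per frame.
    """
    return Scenario([], fps=fps, trial_s=trial_s, seed=seed, trial_id=f"still_{seed}",
                    idle_sigma_px=0.15, pup_idle_sigma_px=0.1,
                    noise=noise if noise is not None else NoiseSpec.jitter_only(0.1))


def sample_scenario(kind: str, seed: int, fps: float = 10.0,
                    noise: Optional[NoiseSpec] = None) -> Scenario:
    factories = {
        "retrieve": retrieval_scenario,
        "no_retrieve": no_retrieval_scenario,
        "nest_shift": nest_shift_scenario,
        "idle": idle_scenario,
    }
    if kind not in factories:
        raise ScenarioError(f"unknown scenario kind {kind!r}")
    return factories[kind](seed=seed, fps=fps, noise=noise)


def training_scenarios(n: int, seed: int, fps: float = 10.0,
                       noise: Optional[NoiseSpec] = None) -> List[Scenario]:
    """A deterministic mixed batch (retrieve / no-retrieve, all with digging)
    whose class prevalences keep the preset undersampling ratios feasible
    (carry must stay under 1/(1+16) of frames for the carry preset)."""
    kinds = ["retrieve", "no_retrieve", "retrieve", "no_retrieve", "no_retrieve"]
    out = []
    for i in range(n):
        out.append(sample_scenario(kinds[i % 5], seed=seed * 1000 + i, fps=fps, noise=noise))
    return out


def write_trial(directory, track: PoseTrack, truth: GroundTruth,
                roi_cfg: ROIConfig, meta: TrialMeta) -> dict:
    """Write a generated trial in the exact formats the pipeline reads.

    Returns the paths written: pose table, annotations, ROI config,
    metadata, and a ground-truth JSON sidecar.
    """
    import json

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "pose": d / "pose.csv",
        "annotations": d / "annotations.csv",
        "roi": d / "roi.yaml",
        "meta": d / "meta.yaml",
        "truth": d / "truth.json",
    }
    write_pose_table(track, paths["pose"])
    write_annotations(truth.labels, paths["annotations"])
    write_roi_config(roi_cfg, paths["roi"])
    write_trial_meta(meta, paths["meta"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "retrieved": truth.retrieved,
            "retrieval_frame": truth.retrieval_frame,
            "retrieval_time_s": (None if truth.retrieval_frame is None
                                 else truth.retrieval_frame / meta.fps),
            "n_outlier_injections": len(truth.outliers),
        }, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
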