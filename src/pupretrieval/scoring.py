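"""Trial-level retrieval scoring.

A trial is scored as a successful retrieval when at least one pup body part
enters the nest ROI and carry behavior was observed within the three
seconds before entry. The carry look-back guards against false positives
from a shifted nest or a pup wandering in on its own: nest occupancy alone
is not retrieval.

Conventions: an "entry" is a false-to-true transition of pup nest
occupancy (frame 0 counts as an entry when the trial starts occupied, but
its look-back window is empty and cannot qualify); the window is
left-closed right-open, [entry - round(3 s * fps), entry), clipped at
frame 0; all entries are scanned in order and the first qualifying one
sets the retrieval time. A trial with no qualifying entry is a failure and
is assigned the maximum trial time (90 s by default) as its retrieval
time, matching the manual scoring convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .classify import labels_to_bouts


class ScoringError(ValueError):
    pass


@dataclass
class BehaviorSummary:
    latency_s: float
    total_duration_s: float
    bout_count: int


@dataclass
class RetrievalResult:
    """Retrieval outcome plus per-behavior latency/duration/count for one trial."""

    trial_id: str
    retrieved: int
    retrieval_time_s: float
    behaviors: Dict[str, BehaviorSummary] = field(default_factory=dict)
    max_trial_s: float = 90.0

    def to_dict(self) -> dict:
        d = {
            "trial_id": self.trial_id,
            "retrieved": int(self.retrieved),
            "retrieval_time_s": float(self.retrieval_time_s),
            "max_trial_s": float(self.max_trial_s),
        }
        for name, b in self.behaviors.items():
            d[f"{name}_latency_s"] = float(b.latency_s)
            d[f"{name}_duration_s"] = float(b.total_duration_s)
            d[f"{name}_bout_count"] = int(b.bout_count)
        return d


def nest_entries(occupancy: np.ndarray) -> np.ndarray:
    """Frames where occupancy flips false->true; frame 0 included if occupied."""
    occ = np.asarray(occupancy, dtype=bool)
    prev = np.concatenate([[False], occ[:-1]])
    return np.flatnonzero(occ & ~prev)


def score_retrieval(pup_nest_occupancy, carry_labels, fps: float,
                    carry_window_s: float = 3.0,
                    max_trial_s: float = 90.0) -> Tuple[int, float]:
    """Decide retrieval success and time from occupancy and carry labels.

    Returns ``(retrieved, retrieval_time_s)``; the time is the qualifying
    entry frame divided by fps, or ``max_trial_s`` when no entry qualifies.
    Carry labels should already be minimum-bout smoothed.
    """
    occ = np.asarray(pup_nest_occupancy, dtype=bool)
    carry = np.asarray(carry_labels, dtype=np.int8)
    if occ.shape != carry.shape:
        raise ScoringError(
            f"occupancy length {occ.size} does not match carry length {carry.size}")
    if fps <= 0:
        raise ScoringError("fps must be positive")
    window = int(round(carry_window_s * fps))
    for e in nest_entries(occ):
        lo = max(0, e - window)
        if np.any(carry[lo:e] == 1):
            return 1, float(e / fps)
    return 0, float(max_trial_s)


def behavior_summary(labels, fps: float, max_trial_s: float = 90.0) -> BehaviorSummary:
    """Latency to first frame, total duration, and bout count for one behavior.

    Latency is ``max_trial_s`` when the behavior never occurs.
    """
    vals = np.asarray(labels, dtype=np.int8)
    if fps <= 0:
        raise ScoringError("fps must be positive")
    present = np.flatnonzero(vals == 1)
    if present.size == 0:
        return BehaviorSummary(float(max_trial_s), 0.0, 0)
    latency = float(present[0] / fps)
    duration = float(present.size / fps)
    count = len(labels_to_bouts(vals))
    return BehaviorSummary(latency, duration, count)


def score_trial(trial_id: str, pup_nest_occupancy, behavior_labels: Dict[str, np.ndarray],
                fps: float, carry_window_s: float = 3.0,
                max_trial_s: float = 90.0,
                carry_behavior: str = "carry") -> RetrievalResult:
    """Full trial result: retrieval decision plus per-behavior summaries."""
    if carry_behavior not in behavior_labels:
        raise ScoringError(f"behavior labels lack {carry_behavior!r}")
    retrieved, t = score_retrieval(
        pup_nest_occupancy, behavior_labels[carry_behavior], fps,
        carry_window_s=carry_window_s, max_trial_s=max_trial_s)
    summaries = {
        name: behavior_summary(vals, fps, max_trial_s)
        for name, vals in behavior_labels.items()
    }
    return RetrievalResult(trial_id, retrieved, t, summaries, max_trial_s)
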