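"""Frame-level random-forest behavior classifiers.

Three binary classifiers (maternal approach, carry, digging) label each
video frame from the feature matrix. Training follows the protocol used to
build the original classifiers:

* 75:25 train/test split of the annotated frames;
* random undersampling of the majority (behavior-absent) class at a
  per-behavior ratio, keeping every behavior-present frame;
* a 2000-tree random forest with entropy splits, sqrt feature subsampling
  and minimum leaf size 1;
* a discrimination threshold chosen on held-out probabilities at the
  highest F1 of the present class (ties resolved toward the lowest
  threshold, favouring sensitivity);
* minimum-bout smoothing: predicted runs shorter than the per-behavior
  minimum bout length are erased.

The fitted per-behavior presets from the original dam-pup dataset
(undersample ratio, threshold, minimum bout length) ship as ``PRESETS``;
they are dataset-specific starting points, not universal constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix

BEHAVIORS = ("approach", "carry", "digging")


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (defaults as fitted in the source protocol)."""

    n_estimators: int = 2000
    criterion: str = "entropy"
    max_features: str = "sqrt"
    min_samples_leaf: int = 1


@dataclass(frozen=True)
class BehaviorPreset:
    undersample_ratio: float
    discrimination_threshold: float
    min_bout_ms: float


#: per-behavior presets fitted on the original dam-pup PRT dataset
PRESETS = {
    "approach": BehaviorPreset(8.5, 0.47, 500.0),
    "carry": BehaviorPreset(16.0, 0.47, 200.0),
    "digging": BehaviorPreset(2.0, 0.24, 1000.0),
}


@dataclass
class FrameLabels:
    """Binary per-frame predictions for one behavior."""

    behavior: str
    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (0, 1)).all():
            raise ClassifyError("frame labels must be binary")


@dataclass
class Bout:
    start: int
    end: int  # inclusive
    behavior: str = ""

    def n_frames(self) -> int:
        return self.end - self.start + 1

    def duration_ms(self, fps: float) -> float:
        return self.n_frames() / fps * 1000.0


@dataclass
class ClassifierBundle:
    """A trained forest plus everything needed to apply it reproducibly."""

    behavior: str
    model: RandomForestClassifier
    discrimination_threshold: float
    min_bout_ms: float
    undersample_ratio: Optional[float]
    seed: int
    registry_version: str
    params: RFParams = field(default_factory=RFParams)

    def __post_init__(self) -> None:
        if not 0 < self.discrimination_threshold < 1:
            raise ClassifyError("discrimination threshold must lie in (0, 1)")
        if self.min_bout_ms < 0:
            raise ClassifyError("min_bout_ms must be >= 0")

    def manifest(self) -> dict:
        return {
            "behavior": self.behavior,
            "discrimination_threshold": self.discrimination_threshold,
            "min_bout_ms": self.min_bout_ms,
            "undersample_ratio": self.undersample_ratio,
            "seed": self.seed,
            "registry_version": self.registry_version,
            "params": {
                "n_estimators": self.params.n_estimators,
                "criterion": self.params.criterion,
                "max_features": self.params.max_features,
                "min_samples_leaf": self.params.min_samples_leaf,
            },
        }


def undersample_majority(labels: np.ndarray, ratio: float, seed: int) -> np.ndarray:
    """Indices keeping all present-class frames plus a sampled absent subset.

    floor(ratio * n_present) behavior-absent frames are drawn without
    replacement; present frames are never dropped. Returned indices are
    sorted ascending.
    """
    labels = np.asarray(labels)
    if ratio <= 0:
        raise ClassifyError("undersample ratio must be positive")
    present = np.flatnonzero(labels == 1)
    absent = np.flatnonzero(labels == 0)
    if present.size == 0 or absent.size == 0:
        raise ClassifyError("both classes must be present to undersample")
    n_select = int(np.floor(ratio * present.size))
    if n_select > absent.size:
        raise ClassifyError(
            f"undersampling needs {n_select} absent frames but only {absent.size} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(absent, size=n_select, replace=False)
    return np.sort(np.concatenate([present, chosen]))


def _as_array(features) -> Tuple[np.ndarray, str]:
    if isinstance(features, FeatureMatrix):
        return features.data.to_numpy(dtype=float), features.version
    return np.asarray(features, dtype=float), "unversioned"


def train_forest(features, labels, behavior: str, params: RFParams = RFParams(),
                 undersample_ratio: Optional[float] = None, test_size: float = 0.25,
                 seed: int = 0, threshold: Optional[float] = None,
                 min_bout_ms: Optional[float] = None):
    """Train a behavior forest on a 75:25 split; returns bundle and held-out scores.

    Undersampling (when a ratio is given) is applied to the training split
    only, so the 25% hold-out keeps the natural class balance for threshold
    selection. Returns ``(bundle, holdout_probs, holdout_labels)`` where the
    probabilities are the present-class scores on the held-out frames. The
    bundle's threshold is selected on those scores at maximum F1 unless an
    explicit ``threshold`` is supplied.
    """
    X, version = _as_array(features)
    y = np.asarray(labels, dtype=np.int8)
    if X.shape[0] != y.shape[0]:
        raise ClassifyError("features and labels are not aligned")
    if np.unique(y).size < 2:
        raise ClassifyError("training data contains a single class")

    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=y)
    if undersample_ratio is not None:
        sel = undersample_majority(y[train_idx], undersample_ratio, seed)
        train_idx = train_idx[sel]
    if np.unique(y[train_idx]).size < 2:
        raise ClassifyError("training split contains a single class")

    model = RandomForestClassifier(
        n_estimators=params.n_estimators,
        criterion=params.criterion,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X[train_idx], y[train_idx])
    holdout_probs = model.predict_proba(X[test_idx])[:, list(model.classes_).index(1)]
    holdout_labels = y[test_idx]

    if threshold is None:
        threshold = select_threshold(holdout_probs, holdout_labels)
    if min_bout_ms is None:
        min_bout_ms = PRESETS[behavior].min_bout_ms if behavior in PRESETS else 0.0

    bundle = ClassifierBundle(
        behavior=behavior, model=model, discrimination_threshold=float(threshold),
        min_bout_ms=float(min_bout_ms), undersample_ratio=undersample_ratio,
        seed=seed, registry_version=version, params=params)
    return bundle, holdout_probs, holdout_labels


def _f1(pred: np.ndarray, labels: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def select_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Discrimination threshold at the highest present-class F1.

    Candidates are the unique probability values united with a 0.01-step
    grid (F1 as a function of the threshold is a step function whose value
    anywhere is attained at one of the observed probabilities, so the
    optimum over this candidate set is the global optimum). Ties break to
    the lowest threshold, favouring sensitivity. Candidates are restricted
    to (0, 1); predictions use probability >= threshold.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if probs.min() < 0 or probs.max() > 1:
        raise ClassifyError("probabilities must lie in [0, 1]")
    if not (y == 1).any():
        raise ClassifyError("threshold selection needs at least one positive label")
    cand = np.union1d(np.unique(probs), np.arange(0.01, 1.0, 0.01))
    cand = cand[(cand > 0) & (cand < 1)]
    if cand.size == 0:
        cand = np.array([0.5])
    f1s = np.array([_f1((probs >= t).astype(np.int8), y) for t in cand])
    best = f1s.max()
    return float(cand[np.flatnonzero(f1s == best)[0]])


def predict_frames(bundle: ClassifierBundle, features) -> FrameLabels:
    """Apply a bundle's forest and threshold; frame is 1 iff prob >= threshold."""
    X, version = _as_array(features)
    if isinstance(features, FeatureMatrix) and version != bundle.registry_version:
        raise ClassifyError(
            f"feature registry version {version} does not match bundle "
            f"({bundle.registry_version})"
        )
    probs = bundle.model.predict_proba(X)[:, list(bundle.model.classes_).index(1)]
    fps = features.fps if isinstance(features, FeatureMatrix) else float("nan")
    return FrameLabels(bundle.behavior,
                       (probs >= bundle.discrimination_threshold).astype(np.int8), fps)


def predict_probabilities(bundle: ClassifierBundle, features) -> np.ndarray:
    X, _ = _as_array(features)
    return bundle.model.predict_proba(X)[:, list(bundle.model.classes_).index(1)]


def min_bout_frames(min_bout_ms: float, fps: float) -> int:
    return max(1, int(round(min_bout_ms / 1000.0 * fps)))


def enforce_min_bout(labels, min_bout_ms: float, fps: float):
    """Erase predicted runs shorter than the minimum bout length.

    A maximal run of 1s shorter than round(min_bout_ms/1000 * fps) frames
    (at least 1) is set to 0; longer runs pass untouched. Never creates 1s,
    hence idempotent and element-wise non-increasing.
    """
    if isinstance(labels, FrameLabels):
        return FrameLabels(labels.behavior,
                           enforce_min_bout(labels.values, min_bout_ms, labels.fps), labels.fps)
    vals = np.asarray(labels, dtype=np.int8).copy()
    need = min_bout_frames(min_bout_ms, fps)
    for bout in labels_to_bouts(vals):
        if bout.n_frames() < need:
            vals[bout.start:bout.end + 1] = 0
    return vals


def labels_to_bouts(labels, behavior: str = "") -> list:
    """Maximal runs of 1s as inclusive (start, end) bouts, in order."""
    if isinstance(labels, FrameLabels):
        return labels_to_bouts(labels.values, labels.behavior)
    vals = np.asarray(labels, dtype=np.int8)
    if vals.size == 0:
        return []
    padded = np.concatenate([[0], vals, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return [Bout(int(s), int(e), behavior) for s, e in zip(starts, ends)]


def bouts_to_labels(bouts, n_frames: int) -> np.ndarray:
    vals = np.zeros(n_frames, dtype=np.int8)
    for b in bouts:
        vals[b.start:b.end + 1] = 1
    return vals


def save_bundle(bundle: ClassifierBundle, directory) -> None:
    """Persist a bundle as model.joblib + manifest.json in a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.model, d / "model.joblib")
    with open(d / "manifest.json", "w") as fh:
        json.dump(bundle.manifest(), fh, indent=2)


def load_bundle(directory) -> ClassifierBundle:
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        m = json.load(fh)
    model = joblib.load(d / "model.joblib")
    return ClassifierBundle(
        behavior=m["behavior"], model=model,
        discrimination_threshold=m["discrimination_threshold"],
        min_bout_ms=m["min_bout_ms"], undersample_ratio=m["undersample_ratio"],
        seed=m["seed"], registry_version=m["registry_version"],
        params=RFParams(**m["params"]))
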