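"""Shared helpers and independent oracles used across test modules."""

import numpy as np

from pupretrieval.pose_io import ANIMALS, PART_NAMES, PoseTrack
from pupretrieval.synthetic import DAM_TEMPLATE, PUP_TEMPLATE

BODY_PARTS = [(a, p) for a in ANIMALS for p in PART_NAMES]


def random_walk_track(rng, n_frames=40, n_jumps=0, step=2.0):
    """Two rigid bodies random-walking with optional injected teleports."""
    coords = np.empty((n_frames, 14, 3))
    dam = np.array([300.0, 300.0])
    pup = np.array([800.0, 500.0])
    for t in range(n_frames):
        dam = dam + rng.normal(0, step, 2)
        pup = pup + rng.normal(0, step, 2)
        coords[t, :7, :2] = dam + DAM_TEMPLATE
        coords[t, 7:, :2] = pup + PUP_TEMPLATE
    coords[:, :, 2] = 1.0
    for _ in range(n_jumps):
        t = int(rng.integers(1, n_frames))
        j = int(rng.integers(0, 14))
        ang = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(150.0, 400.0)
        coords[t, j, :2] += mag * np.array([np.cos(ang), np.sin(ang)])
    return PoseTrack(coords, list(BODY_PARTS), fps=10.0, unit="px")


def random_simple_polygon(rng, k_min=5, k_max=10):
    """Star-shaped polygon with angular gaps < pi, hence always simple."""
    k = int(rng.integers(k_min, k_max + 1))
    ang = (np.arange(k) + rng.uniform(0.0, 0.9, k)) * 2 * np.pi / k
    r = rng.uniform(0.5, 5.0, k)
    return np.c_[r * np.cos(ang), r * np.sin(ang)]


def ray_casting_contains(point, polygon, eps=1e-12):
    """Independent even-odd point-in-polygon oracle; boundary counts inside."""
    x, y = float(point[0]), float(point[1])
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # boundary check: point on segment
        dx, dy = x2 - x1, y2 - y1
        cross = (x - x1) * dy - (y - y1) * dx
        if abs(cross) < eps * max(1.0, abs(dx) + abs(dy)):
            dot = (x - x1) * dx + (y - y1) * dy
            if -eps <= dot <= dx * dx + dy * dy + eps:
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * dx / dy
            if x < x_int:
                inside = not inside
    return inside


def f1_score_manual(pred, labels):
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def trial_features(scenario):
    """Generate a trial and run it through preprocessing + feature extraction."""
    from pupretrieval import (calibrate, compute_criteria, correct_outliers,
                              extract_features, to_mm)
    from pupretrieval.synthetic import generate_trial

    track, truth, roi, meta = generate_trial(scenario)
    crit = compute_criteria(track)
    corrected, _ = correct_outliers(track, crit)
    calib = calibrate(*meta.calibration_px, reference_mm=meta.calibration_reference_mm)
    track_mm = to_mm(corrected, calib)
    fmat = extract_features(track_mm, roi.scaled(calib.scale), fps=meta.fps)
    return fmat, truth, track_mm, roi.scaled(calib.scale)


def bout_recovery_fraction(true_labels, pred_labels):
    """Fraction of true bouts overlapped >= 50% by predicted-present frames."""
    from pupretrieval.classify import labels_to_bouts

    true_bouts = labels_to_bouts(true_labels)
    if not true_bouts:
        return 1.0
    pred = np.asarray(pred_labels)
    hits = sum(
        1 for b in true_bouts
        if pred[b.start:b.end + 1].sum() >= 0.5 * b.n_frames()
    )
    return hits / len(true_bouts)
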