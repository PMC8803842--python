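import numpy as np
import pytest
from hypothesis import given, strategies as st

from tests_support import f1_score_manual

from pupretrieval.classify import (PRESETS, Bout, ClassifyError, FrameLabels,
                                   RFParams, bouts_to_labels, enforce_min_bout,
                                   labels_to_bouts, load_bundle, min_bout_frames,
                                   predict_frames, save_bundle, select_threshold,
                                   train_forest, undersample_majority)


class TestUndersample:
    def test_table_ratio_example(self):
        # 100 present at ratio 8.5 -> 850 absent kept, 950 frames total
        labels = np.r_[np.ones(100, dtype=int), np.zeros(5000, dtype=int)]
        idx = undersample_majority(labels, ratio=8.5, seed=1)
        assert idx.size == 950
        assert (labels[idx] == 1).sum() == 100
        assert (labels[idx] == 0).sum() == 850

    def test_present_frames_never_dropped(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(400) < 0.2).astype(int)
        idx = undersample_majority(labels, ratio=1.5, seed=3)
        present = np.flatnonzero(labels == 1)
        assert np.isin(present, idx).all()

    def test_infeasible_ratio_reports_counts(self):
        labels = np.r_[np.ones(100, dtype=int), np.zeros(200, dtype=int)]
        with pytest.raises(ClassifyError, match="850.*200"):
            undersample_majority(labels, ratio=8.5, seed=0)

    def test_seed_reproducibility(self):
        labels = np.r_[np.ones(50, dtype=int), np.zeros(1000, dtype=int)]
        a = undersample_majority(labels, 4.0, seed=7)
        b = undersample_majority(labels, 4.0, seed=7)
        c = undersample_majority(labels, 4.0, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def separable_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    X = rng.normal(0, 1, (n, 5))
    X[:, 0] += 6.0 * y  # cleanly separable on the first feature
    return X, y


class TestTrainForest:
    def test_defaults_match_protocol(self):
        p = RFParams()
        assert p.n_estimators == 2000
        assert p.criterion == "entropy"
        assert p.max_features == "sqrt"
        assert p.min_samples_leaf == 1

    def test_separable_data_perfect_holdout(self):
        X, y = separable_data()
        bundle, probs, held = train_forest(
            X, y, "carry", params=RFParams(n_estimators=50), seed=1)
        pred = (probs >= bundle.discrimination_threshold).astype(int)
        assert f1_score_manual(pred, held) == 1.0

    def test_fixed_seed_is_deterministic(self):
        X, y = separable_data(seed=2)
        b1, p1, h1 = train_forest(X, y, "carry", params=RFParams(n_estimators=30), seed=5)
        b2, p2, h2 = train_forest(X, y, "carry", params=RFParams(n_estimators=30), seed=5)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(h1, h2)
        assert b1.discrimination_threshold == b2.discrimination_threshold

    def test_single_class_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(ClassifyError, match="single class"):
            train_forest(X, np.zeros(50, dtype=int), "carry")

    def test_undersampling_applied_to_training_split_only(self):
        X, y = separable_data(n=800, seed=3)
        _, probs, held = train_forest(
            X, y, "carry", params=RFParams(n_estimators=30),
            undersample_ratio=1.0, seed=1)
        # hold-out keeps the natural balance: 25% of the frames
        assert held.size == 200

    def test_bundle_round_trip(self, tmp_path):
        X, y = separable_data(seed=4)
        bundle, _, _ = train_forest(X, y, "digging",
                                    params=RFParams(n_estimators=20), seed=2)
        save_bundle(bundle, tmp_path / "dig")
        back = load_bundle(tmp_path / "dig")
        assert back.behavior == "digging"
        assert back.discrimination_threshold == bundle.discrimination_threshold
        assert back.min_bout_ms == PRESETS["digging"].min_bout_ms
        assert back.params == bundle.params
        np.testing.assert_array_equal(
            back.model.predict_proba(X), bundle.model.predict_proba(X))


class TestSelectThreshold:
    def test_perfect_probabilities_pick_lowest_candidate(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        t = select_threshold(y.astype(float), y)
        assert t == pytest.approx(0.01)
        assert f1_score_manual((y.astype(float) >= t).astype(int), y) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ClassifyError, match="positive"):
            select_threshold(np.array([0.1, 0.2]), np.array([0, 0]))

    @given(seed=st.integers(0, 50))
    def test_never_beaten_by_fine_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        y = (rng.random(n) < 0.3).astype(int)
        if not y.any():
            y[0] = 1
        probs = np.clip(rng.normal(0.3 + 0.3 * y, 0.2), 0, 1)
        t = select_threshold(probs, y)
        best = f1_score_manual((probs >= t).astype(int), y)
        grid = np.arange(0.001, 1.0, 0.001)
        grid_best = max(f1_score_manual((probs >= g).astype(int), y) for g in grid)
        assert best >= grid_best - 1e-12

    def test_preset_thresholds_exposed(self):
        assert PRESETS["approach"].discrimination_threshold == 0.47
        assert PRESETS["carry"].discrimination_threshold == 0.47
        assert PRESETS["digging"].discrimination_threshold == 0.24
        assert PRESETS["approach"].min_bout_ms == 500.0
        assert PRESETS["carry"].min_bout_ms == 200.0
        assert PRESETS["digging"].min_bout_ms == 1000.0
        assert (PRESETS["approach"].undersample_ratio,
                PRESETS["carry"].undersample_ratio,
                PRESETS["digging"].undersample_ratio) == (8.5, 16.0, 2.0)


class TestPredictFrames:
    def test_probability_at_threshold_is_present(self):
        X, y = separable_data(seed=5)
        bundle, _, _ = train_forest(X, y, "carry", params=RFParams(n_estimators=40),
                                    seed=1, threshold=0.47)
        probs = bundle.model.predict_proba(X)[:, 1]
        labels = predict_frames(bundle, X)
        np.testing.assert_array_equal(labels.values, (probs >= 0.47).astype(int))

    def test_registry_mismatch_rejected(self, make_track, square_roi):
        from pupretrieval.features import extract_features
        track = make_track(n_frames=40, jitter=3.0, unit="mm")
        fmat = extract_features(track, square_roi, fps=10)
        y = np.zeros(fmat.n_frames, dtype=int)
        y[::3] = 1
        bundle, _, _ = train_forest(fmat, y, "carry",
                                    params=RFParams(n_estimators=10), seed=0)
        fmat_other = extract_features(track, square_roi, fps=10, windows_s=(0.5,))
        with pytest.raises(ClassifyError, match="registry"):
            predict_frames(bundle, fmat_other)


class TestMinBout:
    def test_frame_math_at_500ms_10fps(self):
        # 500 ms at 10 fps = 5 frames: a 4-frame run dies, a 5-frame run lives
        labels = np.zeros(30, dtype=int)
        labels[2:6] = 1   # 4 frames
        labels[10:15] = 1  # 5 frames
        out = enforce_min_bout(labels, 500.0, fps=10)
        assert not out[2:6].any()
        assert out[10:15].all()
        assert min_bout_frames(500.0, 10) == 5

    def test_all_zero_unchanged(self):
        out = enforce_min_bout(np.zeros(20, dtype=int), 1000.0, fps=10)
        assert not out.any()

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80),
           st.sampled_from([200.0, 500.0, 1000.0]))
    def test_idempotent_and_non_increasing(self, bits, min_ms):
        labels = np.array(bits, dtype=np.int8)
        once = enforce_min_bout(labels, min_ms, fps=10)
        twice = enforce_min_bout(once, min_ms, fps=10)
        assert (once <= labels).all()
        np.testing.assert_array_equal(once, twice)

    def test_frame_labels_wrapper(self):
        fl = FrameLabels("carry", np.array([1, 1, 0, 1]), fps=10.0)
        out = enforce_min_bout(fl, 200.0, fps=10.0)
        assert isinstance(out, FrameLabels)
        np.testing.assert_array_equal(out.values, [1, 1, 0, 0])


class TestBouts:
    @pytest.mark.parametrize("labels,expected", [
        ([0, 0, 0], []),
        ([0, 1, 1, 0, 1], [(1, 2), (4, 4)]),
        ([1, 1, 1], [(0, 2)]),
    ])
    def test_run_length_examples(self, labels, expected):
        bouts = labels_to_bouts(np.array(labels))
        assert [(b.start, b.end) for b in bouts] == expected

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_round_trip_identity(self, bits):
        labels = np.array(bits, dtype=np.int8)
        bouts = labels_to_bouts(labels)
        np.testing.assert_array_equal(bouts_to_labels(bouts, len(labels)), labels)
        assert labels_to_bouts(bouts_to_labels(bouts, len(labels))) == bouts

    def test_bout_duration(self):
        assert Bout(3, 7).duration_ms(10.0) == pytest.approx(500.0)
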