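import numpy as np
import pytest

from pupretrieval import (compute_criteria, correct_outliers, roi_occupancy,
                          score_retrieval)
from pupretrieval.synthetic import (Episode, NoiseSpec, Scenario, ScenarioError,
                                    generate_trial, idle_scenario,
                                    inject_tracking_noise, nest_shift_scenario,
                                    no_retrieval_scenario, retrieval_scenario,
                                    sample_scenario, stationary_scenario,
                                    write_trial)


class TestScenarioValidation:
    def test_overlapping_episodes_rejected(self):
        eps = [Episode("approach", 0, 10), Episode("dig", 8, 20)]
        with pytest.raises(ScenarioError, match="overlap"):
            Scenario(eps)

    def test_episode_beyond_trial_rejected(self):
        with pytest.raises(ScenarioError, match="after the trial"):
            Scenario([Episode("dig", 80, 95)], trial_s=90)

    def test_carry_without_approach_warns_only(self):
        with pytest.warns(UserWarning, match="no prior approach"):
            sc = Scenario([Episode("carry", 10, 20)])
        assert sc.episodes[0].behavior == "carry"

    def test_dict_round_trip(self):
        sc = retrieval_scenario(seed=4)
        back = Scenario.from_dict(sc.to_dict())
        assert back.trial_id == sc.trial_id
        assert [e.behavior for e in back.episodes] == [e.behavior for e in sc.episodes]
        t1, *_ = generate_trial(sc)
        t2, *_ = generate_trial(back)
        np.testing.assert_array_equal(t1.coords, t2.coords)


class TestGenerateTrial:
    def test_idle_only_trial_is_all_negative(self):
        track, truth, roi, meta = generate_trial(idle_scenario(seed=2))
        assert all(not v.any() for v in truth.labels.values())
        assert not truth.pup_in_nest.any()
        assert truth.retrieved == 0 and truth.retrieval_frame is None
        assert track.n_frames == 900 and meta.fps == 10.0

    def test_same_seed_bit_identical(self):
        sc = retrieval_scenario(seed=9)
        t1, *_ = generate_trial(sc)
        t2, *_ = generate_trial(sc)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_scripted_entry_time_matches_occupancy(self):
        sc = retrieval_scenario(seed=11, entry_s=30.0, noise=NoiseSpec.none())
        track, truth, roi, meta = generate_trial(sc)
        first = int(np.flatnonzero(truth.pup_in_nest)[0])
        assert abs(first - 300) <= 1
        assert truth.retrieval_frame == first

    def test_occupancy_consistent_with_track(self):
        sc = retrieval_scenario(seed=3, noise=NoiseSpec.jitter_only(1.0))
        track, truth, roi, meta = generate_trial(sc)
        np.testing.assert_array_equal(
            truth.pup_in_nest, roi_occupancy(track, roi, "pup", "any", "nest"))

    def test_carry_frames_respect_coupling_distance(self):
        sc = retrieval_scenario(seed=5, noise=NoiseSpec.none())
        track, truth, roi, meta = generate_trial(sc)
        coupling_px = 10.0 * 2.0  # default coupling_mm at 2 px/mm
        nose = track.xy("dam", "nose")
        pup_centroid = track.coords[:, track.animal_indices("pup"), :2].mean(axis=1)
        d = np.linalg.norm(nose - pup_centroid, axis=1)
        carry = truth.labels["carry"].astype(bool)
        assert carry.any()
        assert d[carry].max() <= coupling_px + 1.0

    def test_approach_closes_distance_over_one_second_windows(self):
        sc = retrieval_scenario(seed=6, noise=NoiseSpec.none())
        track, truth, roi, meta = generate_trial(sc)
        nose = track.xy("dam", "nose")
        pup_centroid = track.coords[:, track.animal_indices("pup"), :2].mean(axis=1)
        d = np.linalg.norm(nose - pup_centroid, axis=1)
        approach = np.flatnonzero(truth.labels["approach"])
        w = int(sc.fps)
        inner = [t for t in approach if t + w in set(approach)]
        assert inner, "approach episode long enough to test"
        drops = [d[t + w] - d[t] for t in inner]
        assert max(drops) < 0  # strictly decreasing over every 1 s window

    def test_ground_truth_closes_loop_with_scoring_rule(self):
        for kind in ("retrieve", "no_retrieve", "nest_shift", "idle"):
            sc = sample_scenario(kind, seed=13, noise=NoiseSpec.jitter_only(1.0))
            track, truth, roi, meta = generate_trial(sc)
            r, t = score_retrieval(truth.pup_in_nest, truth.labels["carry"], sc.fps,
                                   max_trial_s=sc.trial_s)
            assert r == truth.retrieved, kind
            if r:
                assert t == pytest.approx(truth.retrieval_frame / sc.fps)

    def test_nest_shift_occupies_without_carry(self):
        track, truth, roi, meta = generate_trial(
            nest_shift_scenario(seed=4, noise=NoiseSpec.jitter_only(1.0)))
        assert truth.pup_in_nest.any()
        assert not truth.labels["carry"].any()
        assert truth.retrieved == 0

    def test_mutually_exclusive_behaviors(self):
        sc = retrieval_scenario(seed=7)
        _, truth, _, _ = generate_trial(sc)
        overlap = truth.labels["carry"] & truth.labels["digging"]
        assert not overlap.any()


class TestInjectNoise:
    def test_zero_rate_is_identity(self, make_track):
        track = make_track(n_frames=50, jitter=0.5, seed=1)
        out, registry = inject_tracking_noise(track, 0.0, 5.0, 0.0, seed=0)
        np.testing.assert_array_equal(out.coords, track.coords)
        assert registry == []

    def test_injection_count_near_binomial_expectation(self):
        track, *_ = generate_trial(idle_scenario(seed=0, noise=NoiseSpec.none()))
        out, registry = inject_tracking_noise(track, 0.01, 5.0, 0.0, seed=3)
        n = 900 * 14
        expected, sd = n * 0.01, np.sqrt(n * 0.01 * 0.99)
        assert abs(len(registry) - expected) <= 3 * sd

    def test_occlusion_drops_likelihood_below_threshold(self):
        track, *_ = generate_trial(idle_scenario(seed=1, noise=NoiseSpec.none()))
        out, _ = inject_tracking_noise(track, 0.0, 5.0, 0.05, seed=2)
        dropped = out.coords[:, :, 2] < 0.2
        assert 0.03 < dropped.mean() < 0.07
        assert (out.coords[:, :, 2][~dropped] >= 0.9).all()

    def test_registry_records_true_locations(self):
        track, *_ = generate_trial(stationary_scenario(seed=2, noise=NoiseSpec.none()))
        out, registry = inject_tracking_noise(track, 0.005, 4.0, 0.0, seed=9)
        assert registry
        for inj in registry[:20]:
            np.testing.assert_allclose(
                track.coords[inj.frame, inj.part_index, :2], inj.true_xy)
            moved = np.linalg.norm(
                out.coords[inj.frame, inj.part_index, :2] - np.asarray(inj.true_xy))
            assert moved > 50  # far beyond any plausible real movement


def test_end_to_end_jump_recovery(make_track):
    sc = stationary_scenario(seed=8)
    track, *_ = generate_trial(
        Scenario([], fps=10, trial_s=90, seed=8, idle_sigma_px=0.15,
                 pup_idle_sigma_px=0.1, noise=NoiseSpec.jitter_only(0.1)))
    noisy, registry = inject_tracking_noise(track, 0.01, 3.0, 0.0, seed=21)
    corrected, _ = correct_outliers(noisy, compute_criteria(noisy))
    restored = sum(
        np.linalg.norm(corrected.coords[i.frame, i.part_index, :2] - np.asarray(i.true_xy)) <= 1.0
        for i in registry)
    assert restored / len(registry) >= 0.95


def test_write_trial_emits_readable_formats(tmp_path):
    from pupretrieval.pose_io import read_annotations, read_pose_table, read_trial_meta
    from pupretrieval.roi import read_roi_config

    sc = retrieval_scenario(seed=1)
    track, truth, roi, meta = generate_trial(sc)
    paths = write_trial(tmp_path / "t1", track, truth, roi, meta)
    back = read_pose_table(paths["pose"], fps=meta.fps)
    np.testing.assert_allclose(back.coords, track.coords, atol=1e-6)
    ann = read_annotations(paths["annotations"], track.n_frames)
    np.testing.assert_array_equal(ann["carry"].values, truth.labels["carry"])
    roi_back = read_roi_config(paths["roi"])
    np.testing.assert_array_equal(roi_back.nest, roi.nest)
    assert read_trial_meta(paths["meta"]).fps == meta.fps
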