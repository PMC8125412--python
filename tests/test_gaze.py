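"""Unit and property tests for the gaze containers and the salience measure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glimpse import (
    GazeDataset,
    GlimpseParams,
    aggregate_to_frames,
    collect_window_points,
    constant_baseline,
    normalize_gaze,
    pair_consistency,
    temporal_salience,
)
from conftest import random_dataset


def brute_force_salience(dataset: GazeDataset, params: GlimpseParams) -> np.ndarray:
    """Literal double loop over all unordered pairs per window (oracle)."""
    out = np.zeros(dataset.n_frames)
    for t in range(1, dataset.n_frames + 1):
        pts = collect_window_points(dataset, t, params.theta_t).points
        n = len(pts)
        if n < 2:
            continue
        close = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]) < params.theta_s:
                    close += 1
        out[t - 1] = 2.0 * close / (n * (n - 1))
    return out


class TestNormalize:
    def test_divides_by_frame_size(self):
        pos = np.array([[[960.0, 540.0], [0.0, 0.0]]])
        ds = GazeDataset(pos, width=1920, height=1080)
        norm = normalize_gaze(ds)
        assert norm.normalized
        np.testing.assert_allclose(norm.positions[0, 0], [0.5, 0.5])
        np.testing.assert_allclose(norm.positions[0, 1], [0.0, 0.0])

    def test_off_screen_retained_and_counted(self):
        pos = np.array([[[-10.0, 540.0]]])
        norm = normalize_gaze(GazeDataset(pos, width=1920, height=1080))
        np.testing.assert_allclose(norm.positions[0, 0], [-10 / 1920, 0.5])
        assert norm.n_off_screen == 1
        assert norm.drop_off_screen().n_missing == 1

    def test_rejects_double_normalization_and_bad_dims(self):
        ds = GazeDataset(np.zeros((1, 1, 2)), width=10, height=10)
        norm = normalize_gaze(ds)
        with pytest.raises(ValueError):
            normalize_gaze(norm)
        with pytest.raises(ValueError):
            GazeDataset(np.zeros((1, 1, 2)), width=0, height=10)


class TestAggregateToFrames:
    def test_averages_within_frame(self):
        raw = pd.DataFrame(
            {"observer": [1, 1], "time": [0.01, 0.02], "x": [0.1, 0.3], "y": [0.1, 0.3]}
        )
        ds = aggregate_to_frames(raw, frame_rate=25, width=1, height=1)
        np.testing.assert_allclose(ds.positions[0, 0], [0.2, 0.2])

    def test_tracker_to_video_rate_groups_twenty_samples(self):
        # 500 Hz tracker, 25 fps video: 20 samples per frame, cleanly averaged
        times = np.arange(40) / 500.0
        raw = pd.DataFrame(
            {"observer": 1, "time": times, "x": np.arange(40.0), "y": 0.0}
        )
        ds = aggregate_to_frames(raw, frame_rate=25, width=100, height=100,
                                 sampling_rate=500)
        assert ds.n_frames == 2
        np.testing.assert_allclose(ds.positions[0, :, 0], [np.mean(range(20)),
                                                           np.mean(range(20, 40))])

    def test_blink_frame_marked_missing(self):
        raw = pd.DataFrame(
            {
                "observer": [1, 1],
                "time": [0.0, 0.05],
                "x": [0.5, np.nan],
                "y": [0.5, np.nan],
            }
        )
        ds = aggregate_to_frames(raw, frame_rate=25, width=1, height=1)
        assert ds.n_frames == 2
        assert np.isnan(ds.positions[0, 1]).all()
        assert collect_window_points(ds, 2, 0).n == 0

    def test_rejects_undersampled_stream(self):
        raw = pd.DataFrame({"observer": [1], "time": [0.0], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError):
            aggregate_to_frames(raw, frame_rate=25, width=1, height=1, sampling_rate=10)

    def test_empty_stream_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="glimpse.gaze"):
            ds = aggregate_to_frames(
                pd.DataFrame(columns=["observer", "time", "x", "y"]),
                frame_rate=25, width=1, height=1,
            )
        assert ds.n_missing == ds.n_observers * ds.n_frames
        assert any("empty" in r.message for r in caplog.records)


class TestWindowCollection:
    def test_interior_window_size(self):
        ds = GazeDataset(np.zeros((58, 30, 2)), 1, 1, normalized=True)
        assert collect_window_points(ds, 15, 5).n == 58 * 11

    def test_boundary_window_clipped(self):
        ds = GazeDataset(np.zeros((4, 30, 2)), 1, 1, normalized=True)
        assert collect_window_points(ds, 1, 5).n == 4 * 6
        assert collect_window_points(ds, 30, 5).n == 4 * 6

    def test_degenerate_window_is_single_frame(self):
        ds = GazeDataset(np.zeros((7, 30, 2)), 1, 1, normalized=True)
        assert collect_window_points(ds, 10, 0).n == 7

    def test_out_of_range_frame(self):
        ds = GazeDataset(np.zeros((1, 5, 2)), 1, 1, normalized=True)
        with pytest.raises(IndexError):
            collect_window_points(ds, 0, 1)
        with pytest.raises(IndexError):
            collect_window_points(ds, 6, 1)


class TestPairConsistency:
    def test_coincident_points_score_one(self):
        assert pair_consistency(np.zeros((5, 2)), 0.1) == 1.0

    def test_hand_enumerated_triple(self):
        pts = np.array([[0.0, 0.0], [0.05, 0.0], [0.3, 0.0]])
        assert pair_consistency(pts, 0.1) == pytest.approx(1 / 3)

    def test_fewer_than_two_points_score_zero(self):
        assert pair_consistency(np.zeros((0, 2)), 0.1) == 0.0
        assert pair_consistency(np.array([[0.2, 0.2]]), 0.1) == 0.0

    def test_strict_inequality_at_threshold(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0]])
        assert pair_consistency(pts, 0.1) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_score_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((int(rng.integers(2, 30)), 2))
        s = pair_consistency(pts, 0.15)
        assert 0.0 <= s <= 1.0
        assert pair_consistency(rng.permutation(pts), 0.15) == s


class TestTemporalSalience:
    def test_all_staring_at_one_point(self):
        ds = GazeDataset(np.full((6, 20, 2), 0.4), 1, 1, normalized=True)
        np.testing.assert_array_equal(np.asarray(temporal_salience(ds)), 1.0)

    def test_requires_normalized_dataset(self):
        ds = GazeDataset(np.zeros((2, 5, 2)), 10, 10, normalized=False)
        with pytest.raises(ValueError):
            temporal_salience(ds)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            ds = random_dataset(rng)
            params = GlimpseParams(theta_s=float(rng.uniform(0.05, 0.4)),
                                   theta_t=int(rng.integers(0, 6)))
            fast = np.asarray(temporal_salience(ds, params))
            np.testing.assert_array_equal(fast, brute_force_salience(ds, params))

    def test_observer_permutation_invariance(self, rng):
        ds = random_dataset(rng, n_obs=5, n_frames=15)
        perm = ds.subset(rng.permutation(5))
        np.testing.assert_array_equal(
            np.asarray(temporal_salience(ds)), np.asarray(temporal_salience(perm))
        )

    def test_pointwise_monotone_in_theta_s(self, rng):
        ds = random_dataset(rng, n_obs=5, n_frames=20)
        prev = None
        for theta_s in (0.05, 0.1, 0.2, 0.4):
            s = np.asarray(temporal_salience(ds, GlimpseParams(theta_s, 3)))
            if prev is not None:
                assert (s >= prev - 1e-12).all()
            prev = s

    def test_smoothing_with_larger_window(self, autocorrelated_scenario):
        from glimpse import generate_gaze

        ds = generate_gaze(autocorrelated_scenario)
        tvs = []
        for theta_t in (0, 1, 3, 7, 12):
            s = np.asarray(temporal_salience(ds, GlimpseParams(0.1, theta_t)))
            tvs.append(np.abs(np.diff(s)).sum())
        assert all(a >= b for a, b in zip(tvs, tvs[1:]))


class TestConstantBaseline:
    def test_constant_values(self):
        s = constant_baseline(5, 0.25)
        np.testing.assert_array_equal(np.asarray(s), np.full(5, 0.25))

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_extremes(self, lam):
        np.testing.assert_array_equal(np.asarray(constant_baseline(3, lam)), lam)

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range(self, lam):
        with pytest.raises(ValueError):
            constant_baseline(3, lam)
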