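import logging

import numpy as np
import pytest

from divebout.behavior import (
    FeatureSeries,
    classify_behavior,
    compute_pct,
    count_pce,
    extract_events,
    extract_features,
    fit_em,
    identify_pce_cluster,
)
from divebout.errors import FitError
from divebout.segmentation import Bout, Dive, detect_dives, segment_bouts
from divebout.sensor_io import AccelTrace


def make_accel(ax, ay, az, fs=25.0):
    n = len(az)
    t = np.arange(n) / fs
    return AccelTrace(t, np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float))


class TestExtractFeatures:
    def test_constant_input(self):
        n = 1000
        acc = make_accel(np.zeros(n), np.zeros(n), np.ones(n))
        f = extract_features(acc)
        np.testing.assert_allclose(f.vedba, 0.0, atol=1e-12)
        np.testing.assert_allclose(f.X[:, f.names.index("odba")], 0.0, atol=1e-12)
        pitch = f.X[:, f.names.index("pitch")]
        np.testing.assert_allclose(pitch, pitch[0])

    def test_sinusoid_odba_mean_2A_over_pi(self):
        fs, A, freq = 25.0, 0.8, 3.5  # whole cycles per static window
        t = np.arange(0, 400, 1 / fs)
        acc = make_accel(A * np.sin(2 * np.pi * freq * t), np.zeros_like(t), np.ones_like(t))
        f = extract_features(acc)
        odba = f.X[:, f.names.index("odba")]
        assert odba.mean() == pytest.approx(2 * A / np.pi, rel=0.02)

    def test_window_too_short_raises(self):
        acc = make_accel(np.zeros(100), np.zeros(100), np.ones(100))
        with pytest.raises(ValueError):
            extract_features(acc, feature_window_s=0.05)

    def test_burst_windows_have_higher_vedba(self, small_trip):
        _cfg, _grid, _gps, _depth, accel, truth = small_trip
        f = extract_features(accel)
        is_pce = truth.window_pce_truth(f.centers_s, f.window_s)
        assert is_pce.any()
        assert f.vedba[is_pce].min() > np.median(f.vedba[~is_pce])


class TestFitEm:
    def test_two_separated_clusters_recovered(self, rng):
        n = 400
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(10, 1, (n, 2))])
        model = fit_em(X, K=2, seed=0)
        means = np.sort(model.means[:, 0])
        assert abs(means[0] - 0) < 0.1 and abs(means[1] - 10) < 0.1
        labels = model.predict_labels(X)
        # agreement up to permutation
        truth = np.repeat([0, 1], n)
        agree = max((labels == truth).mean(), (labels != truth).mean())
        assert agree > 0.99

    def test_k1_equals_sample_moments(self, rng):
        X = rng.normal(2.0, 1.5, (500, 3))
        model = fit_em(X, K=1, seed=0, n_init=1)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(model.covariances[0], np.cov(X.T, bias=True),
                                   rtol=1e-4, atol=1e-4)

    def test_same_seed_identical_model(self, rng):
        X = rng.normal(size=(300, 4))
        a = fit_em(X, K=3, seed=5)
        b = fit_em(X, K=3, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.loglik == b.loglik

    def test_loglik_monotone_nondecreasing(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 3)), rng.normal(4, 2, (200, 3))])
        model = fit_em(X, K=3, seed=1, n_init=2)
        diffs = np.diff(model.loglik_path)
        assert np.all(diffs > -1e-6 * np.abs(model.loglik_path[1:]))

    def test_degenerate_features_raise(self):
        X = np.ones((100, 3))
        with pytest.raises(FitError):
            fit_em(X, K=2, seed=0)

    def test_too_few_windows_raise(self, rng):
        with pytest.raises(FitError):
            fit_em(rng.normal(size=(10, 5)), K=3, seed=0)

    def test_agrees_with_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        X = np.vstack([rng.normal(0, 1, (300, 2)), rng.normal(6, 1.5, (300, 2))])
        ours = fit_em(X, K=2, seed=0)
        ref = sklearn.GaussianMixture(2, n_init=3, random_state=0).fit(X)
        ours_means = ours.means[np.argsort(ours.means[:, 0])]
        ref_means = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours_means, ref_means, atol=0.05)
        assert ours.loglik / X.shape[0] == pytest.approx(ref.score(X), abs=1e-3)


class TestIdentifyPceCluster:
    def _features(self, vedba):
        n = len(vedba)
        X = np.zeros((n, len(FeatureSeries.__dataclass_fields__["names"].default)))
        from divebout.behavior import VEDBA_COL

        X[:, VEDBA_COL] = vedba
        return FeatureSeries(centers_s=np.arange(n) + 0.5, X=X, window_s=1.0)

    def test_identifies_true_burst_cluster(self, small_trip):
        _cfg, _grid, _gps, depth, accel, truth = small_trip
        dives = detect_dives(depth)
        f = extract_features(accel)
        model = fit_em(f, K=4, seed=0)
        k = identify_pce_cluster(model, f, dives)
        labels = model.predict_labels(f.X)
        is_pce = truth.window_pce_truth(f.centers_s, f.window_s)
        # the identified component is the dominant label among true burst
        # windows (EM may shave partial-overlap boundary windows into a
        # second component on a short trip)
        counts = np.bincount(labels[is_pce], minlength=model.K)
        assert k == counts.argmax()
        assert (labels[is_pce] == k).mean() > 0.5

    def test_k1_returns_zero_with_warning(self, rng, caplog):
        f = self._features(rng.uniform(0, 1, 100))
        model = fit_em(np.column_stack([f.X[:, :1] + rng.normal(0, 0.1, (100, 1))]),
                       K=1, seed=0, n_init=1)
        with caplog.at_level(logging.WARNING):
            assert identify_pce_cluster(model, f) == 0
        assert "single-component" in caplog.text


class TestExtractEvents:
    def _series(self, n, window_s=1.0):
        X = np.zeros((n, 12))
        centers = np.arange(n) * window_s + window_s / 2
        return FeatureSeries(centers_s=centers, X=X, window_s=window_s)

    def test_run_lengths_within_one_dive(self):
        f = self._series(4)
        dives = [Dive(start_s=0.0, end_s=4.0, max_depth_m=5.0, dive_id=0)]
        events = extract_events(np.array([1, 1, 0, 1]), f, dives, pce_component=1)
        assert len(events) == 2
        assert sorted(e.duration_s for e in events) == [1.0, 2.0]

    def test_run_outside_dives_discarded(self):
        f = self._series(6)
        dives = [Dive(start_s=0.0, end_s=2.0, max_depth_m=5.0, dive_id=0)]
        labels = np.array([0, 0, 0, 1, 1, 0])  # run at t=[3,5), outside the dive
        assert extract_events(labels, f, dives, pce_component=1) == []

    def test_short_runs_dropped(self):
        f = self._series(5, window_s=0.1)
        dives = [Dive(start_s=0.0, end_s=1.0, max_depth_m=5.0, dive_id=0)]
        labels = np.array([0, 1, 0, 0, 0])  # 0.1 s run < 0.2 s minimum
        assert extract_events(labels, f, dives, pce_component=1) == []

    def test_adjacent_runs_merged(self):
        f = self._series(5, window_s=0.4)
        dives = [Dive(start_s=0.0, end_s=2.0, max_depth_m=5.0, dive_id=0)]
        labels = np.array([1, 1, 0, 1, 1])
        # gap between runs is 0.4 s = one window -> kept separate;
        # but runs abutting (gap < window) merge
        events = extract_events(labels, f, dives, pce_component=1)
        assert len(events) == 2


class TestCountsAndPct:
    def test_pct_additivity(self):
        d1 = Dive(0, 60, 5, dive_id=0)
        d2 = Dive(100, 160, 5, dive_id=1)
        bout = Bout(bout_id=0, dives=[d1, d2])
        from divebout.behavior import PceEvent

        events = [PceEvent(10, 13, 0), PceEvent(110, 117, 1)]
        assert compute_pct(bout, events) == 10.0
        assert count_pce(d1, events) == 1

    def test_dive_without_events(self):
        d = Dive(0, 60, 5, dive_id=0)
        assert count_pce(d, []) == 0

    def test_pct_equals_sum_of_dive_event_time(self, small_trip):
        _cfg, _grid, _gps, depth, accel, _truth = small_trip
        dives = detect_dives(depth)
        bouts = segment_bouts(dives)
        events, _model, _f = classify_behavior(accel, dives, bouts, K=4, seed=0)
        total_by_bout = sum(b.pct_s for b in bouts)
        total_by_event = sum(e.duration_s for e in events)
        assert total_by_bout == pytest.approx(total_by_event, abs=1e-9)

    def test_label_permutation_invariance(self, small_trip):
        _cfg, _grid, _gps, depth, accel, _truth = small_trip
        dives = detect_dives(depth)
        f = extract_features(accel)
        model = fit_em(f, K=3, seed=2)
        k = identify_pce_cluster(model, f, dives)
        labels = model.predict_labels(f.X)
        ev1 = extract_events(labels, f, dives, k)
        # relabel components by a permutation
        perm = np.array([2, 0, 1])
        ev2 = extract_events(perm[labels], f, dives, perm[k])
        assert [(e.start_s, e.end_s) for e in ev1] == [(e.start_s, e.end_s) for e in ev2]


class TestNoSignalRobustness:
    def test_ratio_one_runs_without_crash_and_near_chance(self):
        from divebout.simulate import SimConfig, simulate_trip

        cfg = SimConfig(seed=21, n_bouts=3, dives_per_bout_mean=8, burst_ratio=1.0)
        _gps, depth, accel, truth = simulate_trip(cfg)
        dives = detect_dives(depth)
        bouts = segment_bouts(dives)
        events, _m, f = classify_behavior(accel, dives, bouts, K=4, seed=0)
        is_pce = truth.window_pce_truth(f.centers_s, f.window_s)
        # no separable signal: detected events need not match truth, but the
        # pipeline completes and true bursts are not preferentially found
        if is_pce.any() and events:
            from divebout.behavior import identify_pce_cluster as ipc
            # nothing to assert strongly; completion without error is the check
        assert isinstance(events, list)
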