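import numpy as np
import pandas as pd
import pytest

from rimla.longitudinal import (
    LesionSeries,
    bootstrap_slopes,
    classify_lesion,
    compute_cov,
    match_scan_rescan,
    run_rimla,
    series_from_csv,
    series_to_csv,
    simulate_volumes,
)
from rimla.synth import SynthConfig, gen_lesion_series


def _series(times, volumes, detected=None, lid="L0"):
    v = np.asarray(volumes, dtype=float)
    det = np.asarray(detected, dtype=bool) if detected is not None else np.isfinite(v)
    return LesionSeries(lid, np.asarray(times, dtype=float), v, det)


class TestCov:
    def test_constant_volumes_have_zero_cov(self):
        cov, mean = compute_cov(np.array([[10.0, 10, 10, 10]]))
        assert cov[0] == 0.0 and mean == 0.0

    def test_hand_computed_cov(self):
        cov, _ = compute_cov(np.array([[8.0, 10, 10, 12]]))
        assert cov[0] == pytest.approx(np.sqrt(8 / 3) / 10)  # 0.16330

    def test_mean_is_unweighted(self):
        vols = np.array([[8.0, 10, 10, 12], [100.0, 100, 100, 100]])
        cov, mean = compute_cov(vols)
        assert mean == pytest.approx(cov.mean())

    def test_single_scan_rejected(self):
        with pytest.raises(ValueError):
            compute_cov(np.array([[10.0]]))

    def test_estimator_consistency(self):
        cfg = SynthConfig(cov_true=0.17, seed=21)
        from rimla.synth import gen_scan_rescan

        sr = gen_scan_rescan(cfg, 500)
        _, mean = compute_cov(sr[[f"scan{i}" for i in range(1, 5)]].to_numpy())
        assert abs(mean - 0.17) / 0.17 < 0.15


class TestSimulateVolumes:
    def test_zero_cov_reproduces_measurements(self):
        s = _series([0, 100, 200], [10, 12, 14])
        draws = simulate_volumes(s, cov=0.0, n_synth=100)
        assert draws.shape == (100, 3)
        assert np.all(draws == np.array([10.0, 12, 14]))

    def test_draw_means_follow_measurements(self):
        s = _series([0, 100, 200], [10, 12, 14])
        draws = simulate_volumes(s, cov=0.17, n_synth=100, seed=5)
        se = 0.17 * np.array([10.0, 12, 14]) / 10  # sd/sqrt(100)
        assert np.all(np.abs(draws.mean(axis=0) - [10, 12, 14]) < 3 * se)
        assert np.all(draws > 0)

    def test_undetected_timepoints_produce_no_draws(self):
        s = _series([0, 100, 200], [np.nan, 12, 14], detected=[False, True, True])
        draws = simulate_volumes(s, cov=0.1, n_synth=50)
        assert draws.shape == (50, 2)


class TestBootstrapSlopes:
    def test_exact_linear_data_gives_constant_slope(self):
        times = np.array([0.0, 100, 200, 300])
        v = 5.0 + 0.02 * times
        draws = np.tile(v, (100, 1))
        slopes, intercepts = bootstrap_slopes(draws, times, n_boot=100, seed=0)
        np.testing.assert_allclose(slopes, 0.02, atol=1e-12)
        np.testing.assert_allclose(intercepts, 5.0, atol=1e-9)

    def test_time_unit_equivariance(self):
        times = np.array([0.0, 182, 365, 548])
        rng = np.random.default_rng(4)
        draws = rng.normal(20, 2, size=(100, 4))
        s_days, _ = bootstrap_slopes(draws, times, seed=7)
        s_years, _ = bootstrap_slopes(draws, times / 365.25, seed=7)
        np.testing.assert_allclose(s_years, s_days * 365.25, rtol=1e-9)

    def test_fewer_than_two_timepoints_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            bootstrap_slopes(np.ones((10, 1)), np.array([0.0]))

    def test_null_slopes_center_on_zero(self):
        times = np.array([0.0, 100, 200, 300, 400])
        s = _series(times, np.full(5, 20.0))
        draws = simulate_volumes(s, cov=0.17, n_synth=100, seed=3)
        slopes, _ = bootstrap_slopes(draws, times, n_boot=1000, seed=3)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) < 5 * se + 1e-4


class TestClassify:
    def _full(self, n=4):
        return _series(np.arange(n) * 100.0, np.full(n, 10.0))

    @pytest.mark.parametrize(
        "n_pos,expected",
        [(100, "enlarging"), (95, "enlarging"), (94, "stable"), (6, "stable"),
         (5, "shrinking"), (0, "shrinking")],
    )
    def test_sign_fraction_threshold_is_inclusive(self, n_pos, expected):
        slopes = np.concatenate([np.ones(n_pos), -np.ones(100 - n_pos)])
        fit = classify_lesion(self._full(), slopes)
        assert fit.label == expected

    def test_all_positive_has_zero_bootstrap_p(self):
        fit = classify_lesion(self._full(), np.ones(100))
        assert fit.label == "enlarging" and fit.bootstrap_p == 0.0
        assert fit.median_slope == 1.0

    def test_new_lesion_has_no_slope(self):
        s = _series([0, 100, 200, 300], [np.nan] * 3 + [10.0],
                    detected=[False, False, False, True])
        fit = classify_lesion(s, None)
        assert fit.label == "new"
        assert np.isnan(fit.median_slope)

    def test_partial_detection_is_discarded(self):
        s = _series([0, 100, 200, 300], [10, np.nan, 11, 12],
                    detected=[True, False, True, True])
        fit = classify_lesion(s, None)
        assert fit.label == "discarded"


class TestRunRimla:
    def test_empty_input_gives_empty_table(self):
        table, counts = run_rimla([], cov=0.17)
        assert len(table) == 0 and counts["stable"] == 0

    def test_scale_invariance(self):
        cfg = SynthConfig(seed=3)
        series = gen_lesion_series(cfg, 20)
        t1, _ = run_rimla(series, cov=0.17, seed=9)
        scaled = [
            LesionSeries(s.lesion_id, s.times, s.volumes * 7.0, s.detected)
            for s in series
        ]
        t2, _ = run_rimla(scaled, cov=0.17, seed=9)
        assert list(t1["label"]) == list(t2["label"])
        np.testing.assert_allclose(
            t2["median_slope_ul_per_day"], t1["median_slope_ul_per_day"] * 7.0,
            rtol=1e-9, equal_nan=True,
        )

    def test_order_independence(self):
        cfg = SynthConfig(seed=13)
        series = gen_lesion_series(cfg, 10)
        t1, _ = run_rimla(series, cov=0.17, seed=2)
        t2, _ = run_rimla(series[::-1], cov=0.17, seed=2)
        merged = t1.merge(t2, on="lesion_id", suffixes=("_a", "_b"))
        assert (merged["label_a"] == merged["label_b"]).all()

    def test_power_monotone_in_slope(self):
        # fraction labelled enlarging must not decrease with the true slope
        rates = []
        for slope in (0.0, 0.03, 0.1, 0.5):
            from rimla.synth import SeriesSpec

            spec = {
                "stable": SeriesSpec(slope),
                "enlarging": SeriesSpec(0.5),
                "shrinking": SeriesSpec(-0.5),
                "new": SeriesSpec(0.0),
            }
            cfg = SynthConfig(seed=31, series_spec=spec)
            series = gen_lesion_series(cfg, 150, classes=["stable"] * 150)
            table, counts = run_rimla(series, cov=0.17, seed=31)
            rates.append(counts["enlarging"] / 150)
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_series_csv_round_trip(self):
        cfg = SynthConfig(seed=6)
        series = gen_lesion_series(cfg, 4)
        df = series_to_csv(series)
        back = series_from_csv(df)
        by_id = {s.lesion_id: s for s in back}
        for s in series:
            r = by_id[s.lesion_id]
            np.testing.assert_array_equal(r.detected, s.detected)
            np.testing.assert_allclose(
                r.volumes[r.detected], s.volumes[s.detected]
            )


class TestMatchScanRescan:
    def _map_with(self, spheres, shape=(16, 16, 16)):
        m = np.zeros(shape, dtype=np.int32)
        for lid, (center, r) in spheres.items():
            g = np.ogrid[tuple(slice(0, s) for s in shape)]
            d2 = sum((gi - c) ** 2 for gi, c in zip(g, center))
            m[d2 <= r**2] = lid
        return m

    def test_identical_maps_match_identically(self):
        m = self._map_with({1: ((5, 5, 5), 2), 2: ((11, 11, 11), 2)})
        table = match_scan_rescan([m, m, m, m], (1.0, 1.0, 1.0))
        assert len(table) == 2
        scans = table[[f"scan{i}" for i in range(1, 5)]].to_numpy()
        assert np.all(scans == scans[:, :1])

    def test_lesion_absent_in_one_scan_excluded(self):
        m1 = self._map_with({1: ((5, 5, 5), 2), 2: ((11, 11, 11), 2)})
        m2 = self._map_with({1: ((5, 5, 5), 2)})
        table = match_scan_rescan([m1, m2, m1, m1], (1.0, 1.0, 1.0))
        assert list(table["lesion_id"]) == [1]

    def test_tie_break_prefers_lower_label(self):
        ref = np.zeros((8, 8, 8), dtype=np.int32)
        ref[2:4, 2:4, 2:4] = 1  # 8 voxels
        other = np.zeros_like(ref)
        other[2:4, 2:4, 2:3] = 2  # overlap 4 with lesion 1
        other[2:4, 2:4, 3:4] = 3  # overlap 4 with lesion 1 -> tie
        table = match_scan_rescan([ref, other], (1.0, 1.0, 1.0))
        # lesion 1 matched to label 2 (lower id); both have 4 voxels = 4 uL
        assert len(table) == 1 and table.loc[0, "scan2"] == 4.0

    def test_fewer_than_two_scans_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            match_scan_rescan([np.zeros((4, 4, 4), dtype=int)], (1, 1, 1))
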