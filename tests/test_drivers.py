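"""Driver attribution: correlations, CUSUM, tidal extremes, TEI/DEI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sgdco2.drivers import (
    CusumCurve,
    correlation_summary,
    cusum_changepoint,
    cusum_driver_response,
    day_night_anchors,
    detect_tidal_extremes,
    peak_hour_means,
    tidal_diel_indices,
)

from conftest import make_series


class TestCorrelations:
    def test_perfect_linear_relation(self):
        rn = np.linspace(1, 10, 50)
        s = make_series(n=50, rn=rn, pco2=2 * rn + 5)
        c = correlation_summary(s)
        assert c["rn"]["r"] == pytest.approx(1.0)
        assert c["rn"]["moderate"] and c["rn"]["significant"]

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(42)
        s = make_series(n=1000, rn=rng.normal(5, 1, 1000), pco2=rng.normal(500, 50, 1000))
        c = correlation_summary(s)
        assert abs(c["rn"]["r"]) < 0.1
        assert not c["rn"]["moderate"]

    def test_constant_channel_flagged_undefined(self):
        s = make_series(n=50, salinity=30.0, pco2=np.linspace(400, 600, 50))
        c = correlation_summary(s)
        assert np.isnan(c["salinity"]["r"])
        assert c["salinity"]["flag"] == "zero_variance"


class TestCusum:
    def test_constant_response_all_zero(self):
        c = cusum_driver_response([1.0, 2.0, 3.0, 4.0], [7.0, 7.0, 7.0, 7.0])
        assert np.all(c.s == 0)
        assert "zero_response_variance" in c.flags

    def test_hand_arithmetic_population_sd(self):
        c = cusum_driver_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        z = 1.0 / np.sqrt(2.0 / 3.0)
        assert c.z == pytest.approx([-z, 0.0, z], abs=1e-4)
        assert c.s == pytest.approx([-1.2247, -1.2247, 0.0], abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_final_sum_zero_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 200)
        c = cusum_driver_response(rng.normal(size=n), rng.normal(size=n))
        assert abs(c.s[-1]) < 1e-9

    def test_invariant_to_affine_response_and_monotone_driver(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=80)
        y = rng.normal(size=80)
        base = cusum_driver_response(d, y)
        affine = cusum_driver_response(3.0 * d + 1.0, -2.0 * y + 7.0)
        # driver affine (increasing) keeps order; response affine flips sign
        assert np.allclose(affine.s, -base.s)

    def test_ties_keep_time_order(self):
        c = cusum_driver_response([2.0, 1.0, 1.0], [10.0, 20.0, 30.0])
        # stable sort: the two driver==1 samples keep their original order
        assert c.z[0] < c.z[1]


class TestChangepoint:
    def test_v_shape_recovered_within_one_rank(self):
        # step response: low below driver 5, high above
        d = np.linspace(0, 10, 40)
        y = np.where(d > 5.0, 10.0, 0.0)
        c = cusum_driver_response(d, y)
        cp = cusum_changepoint(c)
        assert cp == pytest.approx(5.0, abs=d[1] - d[0] + 0.26)

    def test_inverted_or_flat_curve_returns_none(self):
        d = np.linspace(0, 10, 40)
        # inverted-V: response falls above the threshold, slope turns
        # negative, so no upward changepoint is reported
        y = np.where(d > 5.0, -10.0, 0.0)
        c = cusum_driver_response(d, y)
        assert cusum_changepoint(c) is None
        flat = CusumCurve(d, np.zeros(40), np.zeros(40), flags=["zero_response_variance"])
        assert cusum_changepoint(flat) is None

    def test_short_curve_rejected(self):
        c = cusum_driver_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cusum_changepoint(c)

    def test_threshold_recovery_on_synthetic_site(self, tidal_sim):
        series, truth = tidal_sim
        pair = series.data[["rn", "pco2"]].dropna()
        c = cusum_driver_response(pair["rn"], pair["pco2"])
        cp = cusum_changepoint(c)
        assert cp is not None
        assert 4.0 <= cp <= 6.0
        assert truth.true_changepoint == 5.0


class TestTidalExtremes:
    def test_pure_sinusoid_extrema_near_analytic_times(self):
        n = 6 * 48  # 6 days at 30 min
        t_h = np.arange(n) * 0.5
        depth = 1.5 + 0.5 * np.sin(2 * np.pi * t_h / 12.42)
        s = make_series(n=n, depth=depth)
        events = detect_tidal_extremes(s.data["depth"])
        highs = [t for t, k in events if k == "high"]
        # first interior high at t = 12.42/4 h = 3.105 h
        t0 = s.data.index[0]
        got_h = (highs[0] - t0).total_seconds() / 3600.0
        assert got_h == pytest.approx(3.105, abs=0.5)
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternation

    def test_constant_depth_classified_nontidal(self):
        s = make_series(n=100, depth=2.0)
        assert detect_tidal_extremes(s.data["depth"]) == []

    def test_noise_robust_extreme_count(self):
        n = 6 * 48
        t_h = np.arange(n) * 0.5
        depth = 1.5 + 0.5 * np.sin(2 * np.pi * t_h / 12.42)
        clean = detect_tidal_extremes(make_series(n=n, depth=depth).data["depth"])
        rng = np.random.default_rng(5)
        noisy_depth = depth * (1 + 0.05 * rng.standard_normal(n))
        noisy = detect_tidal_extremes(make_series(n=n, depth=noisy_depth).data["depth"])
        assert len(noisy) == len(clean)


class TestPeakHourMeans:
    def test_single_sample_at_anchor(self):
        s = make_series(n=10, step_min=30, pco2=np.arange(10, dtype=float))
        t = s.data.index[4]
        rows, skipped = peak_hour_means(s, [(t, "low")], window_h=0.01, columns=["pco2"])
        assert skipped == 0
        assert rows[0]["pco2"] == 4.0

    def test_linear_ramp_mean_is_midpoint(self):
        s = make_series(n=9, step_min=30, pco2=np.linspace(0, 8, 9))
        t = s.data.index[4]
        rows, _ = peak_hour_means(s, [(t, "high")], columns=["pco2"])
        assert rows[0]["pco2"] == pytest.approx(4.0)

    def test_empty_window_skipped(self):
        s = make_series(n=10, step_min=30)
        rows, skipped = peak_hour_means(
            s, [(s.data.index[0] - pd.Timedelta(hours=10), "low")], columns=["pco2"]
        )
        assert rows == [] and skipped == 1


class TestTidalDielIndices:
    def test_hand_arithmetic(self):
        # eta_H=120, eta_L=80, eta_bar=100 -> TEI 0.2; eta_D=90, eta_N=110 -> DEI -0.1
        tei = (120.0 - 80.0) / (2 * 100.0)
        dei = (90.0 - 110.0) / (2 * 100.0)
        assert tei == pytest.approx(0.2)
        assert dei == pytest.approx(-0.1)
        assert abs(tei) / abs(dei) == pytest.approx(2.0)

    def test_equal_high_low_gives_zero_tei(self):
        n = 6 * 48
        t_h = np.arange(n) * 0.5
        depth = 1.5 + 0.5 * np.sin(2 * np.pi * t_h / 12.42)
        s = make_series(n=n, depth=depth, pco2=500.0)
        events = detect_tidal_extremes(s.data["depth"])
        ti = tidal_diel_indices(s, events, "pco2")
        assert ti.tei == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, tidal_sim):
        series, _ = tidal_sim
        events = detect_tidal_extremes(series.data["depth"])
        base = tidal_diel_indices(series, events, "pco2")
        scaled = series.copy()
        scaled.data["pco2"] *= 3.7
        res = tidal_diel_indices(scaled, events, "pco2")
        assert res.tei == pytest.approx(base.tei, rel=1e-12)
        assert res.dei == pytest.approx(base.dei, rel=1e-12)

    def test_tidal_vs_diel_discrimination(self, tidal_sim, diel_sim):
        for (series, _), expect_tidal in ((tidal_sim, True), (diel_sim, False)):
            events = detect_tidal_extremes(series.data["depth"])
            ti = tidal_diel_indices(series, events, "pco2")
            if expect_tidal:
                assert ti.dominance > 2.0
            else:
                assert ti.dominance < 0.5

    def test_low_tide_co2_peak_sign_conventions(self, tidal_sim):
        # discharge peaks at low tide: pCO2-Rn correlation positive and
        # TEI(pCO2) negative (pCO2 higher at low tide)
        series, _ = tidal_sim
        c = correlation_summary(series)
        assert c["rn"]["r"] > 0 and c["rn"]["significant"]
        events = detect_tidal_extremes(series.data["depth"])
        ti = tidal_diel_indices(series, events, "pco2")
        assert ti.tei < 0

    def test_anchors_within_record(self):
        s = make_series(n=100, step_min=30)
        anchors = day_night_anchors(s.data.index)
        assert all(s.data.index[0] <= t <= s.data.index[-1] for t, _ in anchors)
        assert {k for _, k in anchors} <= {"day", "night"}
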