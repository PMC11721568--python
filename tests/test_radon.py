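"""Radon mass-balance estimators and Monte-Carlo uncertainty."""

from dataclasses import replace
from functools import partial

import numpy as np
import pandas as pd
import pytest

from sgdco2.radon import (
    LAMBDA_222,
    RadonBudgetTerms,
    RadonMassBalance,
    monte_carlo_uncertainty,
    nonsteady_sgd,
    steady_state_sgd,
    tidal_cycle_integrated_sgd,
)

from conftest import make_series


def quiet_terms(**kw):
    base = dict(rn_gw=1e5, a=1e4, v=1e4, atm_rn=0.0)
    base.update(kw)
    return RadonBudgetTerms(**base)


class TestSteadyState:
    def test_decay_constant_value(self):
        assert LAMBDA_222 == pytest.approx(0.1813, abs=2e-4)

    def test_balanced_budget_gives_zero(self):
        t = quiet_terms(rn=0.0, f_up_rn_up=500.0, f_down_rn_down=500.0)
        assert steady_state_sgd(t).f_gw == 0.0

    def test_only_decay_sink_hand_algebra(self):
        t = quiet_terms(rn=1000.0, v=1000.0)
        est = steady_state_sgd(t)
        assert est.f_gw == pytest.approx(1000.0 * LAMBDA_222 * 1000.0 / 1e5, rel=1e-12)
        assert est.f_gw == pytest.approx(1.81, abs=0.01)

    def test_linear_in_inverse_endmember(self):
        t = quiet_terms(rn=1000.0)
        t2 = replace(t, rn_gw=2e5)
        assert steady_state_sgd(t2).f_gw == pytest.approx(steady_state_sgd(t).f_gw / 2)

    def test_negative_budget_clipped_and_flagged(self):
        t = quiet_terms(rn_gw=1e5, rn=1e5, f_up_rn_up=1e9)
        with pytest.warns(UserWarning):
            est = steady_state_sgd(t)
        assert est.f_gw == 0.0
        assert est.f_gw_raw < 0
        assert "negative_f_gw_clipped" in est.flags

    def test_budget_closure(self):
        t = quiet_terms(rn=2000.0, j_atm=3e5, d_dif=100.0, ra226=50.0, q_ex=0.7)
        est = steady_state_sgd(t)
        total = sum(v for k, v in est.term_budget.items() if k != "groundwater")
        assert est.term_budget["groundwater"] == pytest.approx(total, rel=1e-9)

    def test_sgd_rate_consistent_with_area(self):
        t = quiet_terms(rn=1000.0)
        est = steady_state_sgd(t)
        assert est.sgd_rate == pytest.approx(100.0 * est.f_gw / t.a)


class TestNonSteady:
    def test_constant_series_zero_sources_gives_zero(self):
        s = make_series(n=48, rn=2.0, depth=1.5, wind=0.0)
        t = quiet_terms(rn_gw=1e5, lambda222=0.0)
        est = nonsteady_sgd(s, t, step=1.0, smooth_window=1)
        assert est.f_gw == pytest.approx(0.0, abs=1e-9)

    def test_linear_rise_matches_finite_difference(self):
        # Rn rising 0.5 dpm/L per hour, no sinks: F_gw = V dC/dt / Rn_gw
        n = 24
        rn = 1.0 + 0.5 * np.arange(n) / 2.0  # 30-min samples
        s = make_series(n=n, step_min=30, rn=rn, depth=2.0, wind=0.0)
        t = quiet_terms(rn_gw=1e5, a=1e4, v=2e4, lambda222=0.0)
        est = nonsteady_sgd(s, t, step=1.0, smooth_window=1)
        # dC/dt = 0.25 dpm/L per 30 min = 1 dpm/L/h * ... in dpm/m3/day:
        expect = (2e4 * 0.5 * 1e3 * 24) / 1e5
        assert est.f_gw == pytest.approx(expect, rel=1e-6)
        assert np.allclose(est.series.to_numpy(), expect, rtol=1e-6)

    def test_matches_steady_state_for_stationary_series(self):
        s = make_series(n=48, rn=3.0, depth=1.5, wind=0.0)
        t = quiet_terms(rn_gw=1e5, rn=3000.0, v=1.5e4)
        ns = nonsteady_sgd(s, t, step=1.0, smooth_window=1)
        ss = steady_state_sgd(t)
        assert ns.f_gw == pytest.approx(ss.f_gw, rel=1e-9)

    def test_too_short_series_rejected(self):
        s = make_series(n=1)
        with pytest.raises(ValueError, match="2 steps"):
            nonsteady_sgd(s, quiet_terms())


class TestTidalCycle:
    @staticmethod
    def _tidal_series(n_cycles=3, step_min=30):
        # 12-h period commensurate with the grid so cycles are sample-identical;
        # radon in phase with depth so the cyclic storage integral closes
        n = int(n_cycles * 12.0 * 60 / step_min) + 1
        t_h = np.arange(n) * step_min / 60.0
        depth = 1.5 + 0.5 * np.cos(2 * np.pi * t_h / 12.0)
        rn = 3.0 + 1.0 * np.cos(2 * np.pi * t_h / 12.0)
        return make_series(n=n, step_min=step_min, depth=depth, rn=rn, wind=0.0)

    def test_periodic_series_identical_cycles(self):
        s = self._tidal_series(3)
        t = quiet_terms(rn_gw=1e5, v=1.5e4)
        est = tidal_cycle_integrated_sgd(s, t)
        vals = est.series.to_numpy()
        assert len(vals) >= 2
        assert np.allclose(vals, vals[0], rtol=1e-6)

    def test_closed_budget_arithmetic(self):
        # periodic inventory (start == end) with decay only: the per-cycle
        # discharge equals the cycle-integrated decay / Rn_gw
        s = self._tidal_series(2)
        t = quiet_terms(rn_gw=1e5, v=1.5e4)
        est = tidal_cycle_integrated_sgd(s, t)
        df = s.data
        events_rate = (
            df["rn"].to_numpy() * 1e3 * LAMBDA_222 * (t.a * df["depth"].to_numpy())
        )
        mean_decay = events_rate.mean()
        assert est.f_gw == pytest.approx(mean_decay / 1e5, rel=0.05)

    def test_no_cycle_raises(self):
        s = make_series(n=48, depth=1.5)  # flat depth: nontidal
        with pytest.raises(ValueError, match="cycle"):
            tidal_cycle_integrated_sgd(s, quiet_terms())


class TestMonteCarlo:
    def test_zero_spreads_zero_uncertainty(self):
        t = quiet_terms(rn=1000.0)
        unc, draws = monte_carlo_uncertainty(steady_state_sgd, t, {"rn_gw": 0.0}, n=200, seed=1)
        assert unc == pytest.approx(0.0, abs=1e-9)
        assert np.all(draws == draws[0])

    def test_endmember_cv_propagates_first_order(self):
        # F ~ 1/Rn_gw: a 20% CV on the end-member gives ~20% output CV
        t = quiet_terms(rn=1000.0)
        unc, _ = monte_carlo_uncertainty(
            steady_state_sgd, t, {"rn_gw": 0.2 * t.rn_gw}, n=4000, seed=3
        )
        assert unc == pytest.approx(20.0, abs=4.0)

    def test_seed_reproducibility(self):
        t = quiet_terms(rn=1000.0)
        a = monte_carlo_uncertainty(steady_state_sgd, t, {"rn_gw": 2e4}, n=300, seed=9)
        b = monte_carlo_uncertainty(steady_state_sgd, t, {"rn_gw": 2e4}, n=300, seed=9)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])

    def test_zero_mean_discharge_flagged_nan(self):
        t = quiet_terms(rn=0.0)  # no sinks: F_gw = 0 always
        with pytest.warns(UserWarning, match="undefined"):
            unc, _ = monte_carlo_uncertainty(steady_state_sgd, t, {"d_dif": 0.0}, n=100, seed=0)
        assert np.isnan(unc)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_uncertainty(steady_state_sgd, quiet_terms(), {}, n=10)


class TestModelObject:
    def test_fit_dispatch_and_summary(self):
        s = make_series(n=48, rn=3.0, depth=1.5, wind=0.0)
        t = quiet_terms(rn_gw=1e5, rn=3000.0, v=1.5e4)
        model = RadonMassBalance(t, s)
        res = model.fit(method="steady", mc_spreads={"rn_gw": 1e4}, mc_draws=200, seed=0)
        assert res.method == "steady_state"
        assert np.isfinite(res.uncertainty_pct)
        text = res.summary()
        assert "SGD rate" in text and "uncertainty" in text

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            RadonMassBalance(quiet_terms()).fit(method="magic")

    def test_series_required_for_time_resolved(self):
        with pytest.raises(ValueError, match="requires a series"):
            RadonMassBalance(quiet_terms()).fit(method="nonsteady")
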