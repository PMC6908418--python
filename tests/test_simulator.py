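"""Diel integration: phase rules, mass closure, periodicity, scenarios."""

import numpy as np
import pytest

from cfm_croco.metabolism import CellState
from cfm_croco.parameters import Parameters
from cfm_croco.simulator import (Scenario, canonical_forcing, daily_integrals,
                                 initial_state, run_diel, run_scenario, scan,
                                 step, trapezoid_daily)


def closure_errors(res):
    """Per-day relative C and N closure errors of the population totals."""
    m = res.parameters.metabolism
    s = res.series
    n = res.steps_per_day
    c_tot = s["x"] * (m.Q_C + s["c_s"])
    n_tot = s["x"] * (m.Q_C * m.Y_bio_NC + s["n_s"])
    c_flux = s["x"] * (s["photo_o2"] - s["co2_bio"] - s["co2_n2fix"]
                       - s["co2_rp"] - s["exc"])
    n_flux = s["x"] * s["n2fix"]
    c_err, n_err = [], []
    for d in range(res.days_run):
        sl = slice(d * n, (d + 1) * n + 1)
        dc = c_tot[sl][-1] - c_tot[sl][0]
        dn = n_tot[sl][-1] - n_tot[sl][0]
        fc = np.trapezoid(c_flux[sl], res.times[sl])
        fn = np.trapezoid(n_flux[sl], res.times[sl])
        c_err.append(abs(dc - fc) / max(abs(c_tot[sl][0]), 1e-300))
        n_err.append(abs(dn - fn) / max(abs(n_tot[sl][0]), 1e-300))
    return max(c_err), max(n_err)


class TestStep:
    def test_dark_step_has_no_photosynthesis(self, params):
        f = canonical_forcing(0.20)
        st = initial_state(f, params)
        st.fe_n = 5e-19
        _, rec = step(st, 15.0, 0.01, f, params)
        assert rec["photo_o2"] == 0.0 and rec["lam"] == 0.0 and rec["exc"] == 0.0

    def test_light_step_has_no_fixation_or_protection(self, params):
        f = canonical_forcing(0.20)
        st = initial_state(f, params)
        st.fe_p, st.fe_b, st.chl = 1e-18, 1e-18, 1e-16
        _, rec = step(st, 6.0, 0.01, f, params)
        assert rec["n2fix"] == 0.0 and rec["co2_n2fix"] == 0.0
        assert rec["co2_rp"] == 0.0

    def test_empty_pools_yield_a_fixed_point(self, params):
        f = canonical_forcing(0.20)
        st = CellState(c_s=0.0, n_s=0.0, fe_p=0.0, fe_b=0.0, fe_n=0.0,
                       chl=0.0, x=1e11, r=2.5e-6)
        out, _ = step(st, 6.0, 0.01, f, params)
        assert (out.c_s, out.n_s, out.fe_p, out.fe_b, out.fe_n, out.chl,
                out.x) == (0.0,) * 6 + (st.x,)


class TestDailyIntegrals:
    def test_constant_flux(self):
        t = np.linspace(0.0, 48.0, 4801)
        assert trapezoid_daily(t, np.full_like(t, 3.0)) == pytest.approx([72.0, 72.0])

    def test_zero_flux(self):
        t = np.linspace(0.0, 24.0, 100)
        assert trapezoid_daily(t, np.zeros_like(t)) == pytest.approx([0.0])

    def test_triangular_profile_closed_form(self):
        t = np.linspace(0.0, 24.0, 2401)
        v = np.where(t <= 12.0, t, 24.0 - t)  # triangle of height 12 at noon
        assert trapezoid_daily(t, v) == pytest.approx([0.5 * 24.0 * 12.0])

    def test_matches_instantaneous_series(self, run20):
        daily = daily_integrals(run20)
        sl = run20.converged_day
        ref = np.trapezoid(run20.series["n2fix"][sl], run20.times[sl])
        assert daily["n2fix"].iloc[-1] == pytest.approx(ref, rel=1e-12)


class TestConservation:
    def test_iron_conserved_along_trajectory(self, run20):
        s = run20.series
        total = s["fe_p"] + s["fe_b"] + s["fe_n"]
        assert np.max(np.abs(total - total[0])) <= 1e-12 * total[0]

    def test_carbon_and_nitrogen_closure(self, run20, run5):
        for res in (run20, run5):
            c_err, n_err = closure_errors(res)
            assert c_err < 5e-3 and n_err < 5e-3

    def test_storage_ceilings_respected(self, run20):
        m = run20.parameters.metabolism
        assert np.max(run20.series["c_s"]) <= m.CSmax
        assert np.max(run20.series["n_s"]) <= m.NSmax


class TestPeriodicSteadyState:
    def test_converged_day_repeats(self, run20):
        assert run20.converged
        n = run20.steps_per_day
        for k in ("c_s", "n_s", "fe_p", "fe_n", "chl"):
            a = run20.series[k][-n - 1:-1]
            b = run20.series[k][-2 * n - 1:-n - 1]
            assert np.max(np.abs(a - b)) <= 2e-4 * np.max(np.abs(a))

    def test_canonical_5pct_o2_eliminated_before_14h(self, run5):
        assert run5.first_zero_o2_hour() < 14.0

    def test_canonical_20pct_o2_eliminated_after_15h(self, run20):
        assert run20.first_zero_o2_hour() > 15.0

    def test_dt_halving_changes_daily_integrals_below_1pct(self):
        f = canonical_forcing(0.20)
        p = Parameters.default()
        coarse = daily_integrals(run_diel(f, p, dt=0.04)).iloc[-1]
        fine = daily_integrals(run_diel(f, p, dt=0.02)).iloc[-1]
        for k in ("photo_o2", "resp_o2", "n2fix"):
            assert coarse[k] == pytest.approx(fine[k], rel=1e-2)


class TestScenarios:
    def test_no_size_change_identical_at_5pct(self, run5):
        alt = run_scenario("no_size_change", canonical_forcing(0.05), dt=0.02)
        for k in ("c_s", "n_s", "o2cell", "n2fix"):
            assert np.array_equal(alt.series[k], run5.series[k])

    def test_no_respiratory_protection_loses_fixation_at_20pct(self, run20):
        alt = run_scenario("no_respiratory_protection", canonical_forcing(0.20),
                           dt=0.02)
        ref = daily_integrals(run20)["n2fix"].iloc[-1]
        assert daily_integrals(alt)["n2fix"].iloc[-1] < ref

    def test_high_diffusivity_overestimates_respiration_at_5pct(self, run5):
        alt = run_scenario("high_diffusivity", canonical_forcing(0.05), dt=0.02)
        assert daily_integrals(alt)["resp_o2"].iloc[-1] > \
            daily_integrals(run5)["resp_o2"].iloc[-1]

    def test_high_diffusivity_suppresses_fixation(self, run20, run5):
        for frac, ref in ((0.20, run20), (0.05, run5)):
            alt = run_scenario("high_diffusivity", canonical_forcing(frac), dt=0.02)
            assert daily_integrals(alt)["n2fix"].iloc[-1] < \
                0.6 * daily_integrals(ref)["n2fix"].iloc[-1]

    def test_fixed_radius_fixation_ordering(self):
        daily = {}
        for frac in (0.05, 0.20):
            res = run_scenario("no_size_change", canonical_forcing(frac), dt=0.02)
            daily[frac] = daily_integrals(res)["n2fix"].iloc[-1]
        assert daily[0.05] >= daily[0.20]

    def test_dark_respiration_higher_at_20pct(self, run20, run5):
        def dark_total(res):
            sl = res.converged_day
            mask = res.clock[sl] >= 12.0
            return np.trapezoid(res.series["resp_o2"][sl][mask],
                                res.times[sl][mask])
        assert dark_total(run20) > dark_total(run5)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario("warp_drive")


class TestScan:
    def test_rejects_unsorted_grid(self, params):
        with pytest.raises(ValueError):
            scan("irradiance", [100.0, 50.0], canonical_forcing(0.20), params)

    def test_small_irradiance_scan_is_monotone_at_low_light(self, params):
        table = scan("irradiance", [0.0, 75.0, 150.0], canonical_forcing(0.20),
                     params, dt=0.04)
        vals = table["n2fix_daily"].to_numpy()
        assert vals[0] == pytest.approx(0.0, abs=1e-22)
        assert vals[1] < vals[2] * 1.05  # low light never beats canonical light
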