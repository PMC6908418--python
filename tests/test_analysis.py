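"""ETR computation, Eilers-Peeters fitting, conversions, fixtures, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cfm_croco.analysis import (FRRSample, acetylene_to_n2, calibrate,
                                eilers_peeters_curve, etr, fit_eilers_peeters,
                                generate_diel_observations, generate_pve_points,
                                _objective)
from cfm_croco.parameters import Parameters

TRUTH_ABC = (1.0e-5, 2.0e-3, 0.4)


def sample(E=100.0, f=0.7, fm=1.0, fo=0.4, sigma=4.0, n=0.002, phi=1.0):
    return FRRSample(E=E, sigma_psii=sigma, f_prime=f, fm_prime=fm,
                     fo_prime=fo, n_psii=n, phi_rcii=phi)


class TestETR:
    def test_darkness_gives_zero(self):
        assert etr(sample(E=0.0)) == 0.0

    def test_fully_open_centers_collapse_the_ratio(self):
        s = sample(f=0.4)  # F' = Fo'
        assert etr(s) == pytest.approx(s.sigma_psii * s.n_psii * s.E)

    def test_hand_evaluated_product(self):
        # Fq'/Fv' = (1.0-0.7)/(1.0-0.4) = 0.5
        assert etr(sample()) == pytest.approx(4.0 * 0.002 * 0.5 * 1.0 * 100.0)

    @given(st.floats(1e-3, 1e3))
    def test_linear_in_actinic_light(self, scale):
        assert etr(sample(E=100.0 * scale)) == pytest.approx(
            scale * etr(sample(E=100.0)), rel=1e-9)

    @given(st.floats(1e-3, 1e3))
    def test_linear_in_cross_section(self, scale):
        assert etr(sample(sigma=4.0 * scale)) == pytest.approx(
            scale * etr(sample()), rel=1e-9)

    def test_degenerate_fluorescence_rejected(self):
        with pytest.raises(Exception):
            etr(sample(f=0.4, fm=0.4, fo=0.4))

    def test_invariant_ordering_enforced(self):
        with pytest.raises(ValueError):
            FRRSample(E=10.0, sigma_psii=4.0, f_prime=1.2, fm_prime=1.0,
                      fo_prime=0.4)


class TestEilersPeeters:
    def test_noiseless_recovery_is_exact(self):
        pts = generate_pve_points(seed=0, truth=TRUTH_ABC, noise_sd=0.0)
        fit = fit_eilers_peeters(pts)
        a, b, c = TRUTH_ABC
        etr_max = 1.0 / (b + 2.0 * np.sqrt(a * c))
        assert fit.etr_max == pytest.approx(etr_max, rel=1e-6)
        assert fit.alpha == pytest.approx(1.0 / c, rel=1e-6)
        assert fit.e_k == pytest.approx(etr_max * c, rel=1e-6)

    def test_one_percent_noise_recovers_within_five_percent(self):
        pts = generate_pve_points(seed=7, truth=TRUTH_ABC, noise_sd=0.01)
        fit = fit_eilers_peeters(pts)
        a, b, c = TRUTH_ABC
        etr_max = 1.0 / (b + 2.0 * np.sqrt(a * c))
        assert fit.etr_max == pytest.approx(etr_max, rel=0.05)
        assert fit.alpha == pytest.approx(1.0 / c, rel=0.05)

    def test_saturation_identity_holds(self):
        pts = generate_pve_points(seed=0, truth=TRUTH_ABC, noise_sd=0.0)
        fit = fit_eilers_peeters(pts)
        assert fit.e_k == pytest.approx(fit.etr_max / fit.alpha, rel=1e-9)

    def test_all_zero_rates_fail_loudly(self):
        pts = [(E, 0.0) for E in (0.0, 50.0, 200.0, 800.0, 1600.0)]
        with pytest.raises(ArithmeticError):
            fit_eilers_peeters(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_eilers_peeters([(0.0, 0.0), (100.0, 1.0), (200.0, 1.5)])


class TestAcetyleneConversion:
    @pytest.mark.parametrize("c2h4,n2,n_atoms", [
        (3.0, 1.0, 2.0), (0.0, 0.0, 0.0), (6.0, 2.0, 4.0)])
    def test_theoretical_factor_three(self, c2h4, n2, n_atoms):
        assert acetylene_to_n2(c2h4) == pytest.approx((n2, n_atoms))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            acetylene_to_n2(-1.0)


class TestFixtures:
    def test_same_seed_reproduces_exactly(self):
        a = generate_pve_points(seed=5, truth=TRUTH_ABC, noise_sd=0.1)
        b = generate_pve_points(seed=5, truth=TRUTH_ABC, noise_sd=0.1)
        assert np.array_equal(a, b)

    def test_zero_noise_lies_on_the_curve(self):
        pts = generate_pve_points(seed=3, truth=TRUTH_ABC, noise_sd=0.0)
        expected = eilers_peeters_curve(pts[:, 0], *TRUTH_ABC)
        assert pts[:, 1] == pytest.approx(expected, rel=1e-12)

    def test_replicate_mean_converges_to_truth(self):
        # law of large numbers over 1000 seeded replicates of one grid point
        curves = np.stack([
            generate_pve_points(seed=s, truth=TRUTH_ABC, noise_sd=0.10)[:, 1]
            for s in range(1000)])
        truth = eilers_peeters_curve(
            generate_pve_points(seed=0, truth=TRUTH_ABC)[:, 0], *TRUTH_ABC)
        sd = 0.10 * truth.max()
        assert np.max(np.abs(curves.mean(axis=0) - truth)) < 5.0 * sd / np.sqrt(1000)

    def test_diel_fixture_records_provenance(self):
        obs = generate_diel_observations(seed=11, noise_sd=0.0, dt=0.05,
                                         max_days=6, treatments=(0.20,))
        assert obs.seed == 11
        assert set(obs.data["channel"]) == {"photo_o2", "resp_o2", "n2fix",
                                            "c_per_cell", "n_per_cell"}
        assert (obs.data["sd"] >= 0).all()

    def test_diel_fixture_same_seed_identical(self):
        kw = dict(noise_sd=0.1, dt=0.1, max_days=4, treatments=(0.05,))
        a = generate_diel_observations(seed=2, **kw)
        b = generate_diel_observations(seed=2, **kw)
        assert a.data.equals(b.data)


class TestCalibrate:
    def test_empty_free_set_returns_start_point(self):
        obs = generate_diel_observations(seed=1, noise_sd=0.0, dt=0.1,
                                         max_days=4, treatments=(0.05,))
        p0 = Parameters.default()
        fitted, diag = calibrate([], obs, p0, dt=0.1, max_days=4)
        assert fitted.get("membrane_factor") == p0.get("membrane_factor")
        assert diag["fitted"] == {}

    def test_unknown_tunable_rejected(self):
        obs = generate_diel_observations(seed=1, noise_sd=0.0, dt=0.1,
                                         max_days=4, treatments=(0.05,))
        with pytest.raises(KeyError):
            calibrate(["flux_capacitance"], obs, Parameters.default())

    def test_objective_rises_away_from_truth(self):
        truth = Parameters.default()
        obs = generate_diel_observations(seed=3, noise_sd=0.0, dt=0.05,
                                         max_days=8)
        at_truth = _objective(truth, obs, dt=0.05, max_days=8)
        perturbed = truth.with_overrides(
            **{"diffusivity.membrane_factor": truth.get("membrane_factor") * 10})
        assert _objective(perturbed, obs, dt=0.05, max_days=8) > at_truth
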