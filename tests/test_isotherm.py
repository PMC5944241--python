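"""Hill/Gouy-Chapman isotherm model, fitting, extrapolation, free energies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepcharge import simulate as sim
from pepcharge.exceptions import DegenerateNormalizationError, InsufficientDataError
from pepcharge.isotherm import (
    GCParams,
    HillGouyChapmanIsotherm,
    IsothermData,
    additive_expectation,
    augment_extrapolated_point,
    fit_isotherm,
    free_energy,
    gc_potential,
    hill_coverage,
    model_efield,
    percent_ionization,
    sensitivity_scan,
)


class TestGCPotential:
    def test_neutral_surface(self):
        assert gc_potential(0.0) == 0.0

    def test_reference_value(self):
        # -0.1 C/m^2 in 0.1 M 1:1 electrolyte at 298.15 K, eps 78.2
        assert gc_potential(-0.1) == pytest.approx(-0.0883, abs=5e-4)

    def test_small_sigma_linear_slope(self):
        p = GCParams()
        sigma = 1e-4 * p.sigma_star
        slope = gc_potential(sigma, p) / sigma
        assert slope == pytest.approx(2 * p.thermal_voltage / p.sigma_star, rel=1e-6)

    @given(sigma=st.floats(-0.5, 0.5))
    @settings(derandomize=True, max_examples=50)
    def test_odd_function(self, sigma):
        assert gc_potential(-sigma) == pytest.approx(-gc_potential(sigma), abs=1e-15)

    def test_strictly_monotone(self):
        s = np.linspace(-0.3, 0.3, 101)
        assert np.all(np.diff(gc_potential(s)) > 0)

    def test_debye_huckel_agreement_at_low_charge(self):
        p = GCParams()
        for frac in (0.01, 0.05, 0.099):
            sigma = frac * p.sigma_star
            linear = 2 * p.thermal_voltage * sigma / p.sigma_star
            assert gc_potential(sigma, p) == pytest.approx(linear, rel=0.01)


class TestHillCoverage:
    def test_half_saturation_for_any_n(self):
        for n in (0.3, 0.54, 1.0, 2.5):
            assert hill_coverage(1e-6, 1e6, n) == pytest.approx(0.5)

    def test_langmuir_special_case(self):
        c = np.logspace(-9, -3, 20)
        k = 1e6
        assert hill_coverage(c, k, 1.0) == pytest.approx(k * c / (1 + k * c))

    def test_hand_value(self):
        assert hill_coverage(1e-6, 1.6e6, 0.54) == pytest.approx(0.563, abs=1e-3)

    def test_monotone_and_bounded(self):
        c = np.logspace(-10, -1, 50)
        theta = hill_coverage(c, 1.6e6, 0.54)
        assert np.all(np.diff(theta) > 0)
        assert np.all((theta >= 0) & (theta <= 1))
        assert hill_coverage(0.0, 1e6, 0.5) == 0.0


class TestModelEfield:
    def test_no_adsorption_is_flat(self):
        c = np.logspace(-9, -2, 10)
        assert model_efield(c, 1.0, -3.8, 1e6, 0.5, 0.0, -0.1) == pytest.approx(np.ones(10))

    def test_normalized_to_one_at_zero_conc(self):
        assert model_efield(0.0, 1.0, -3.8, 1e6, 0.5, 0.1, -0.1) == pytest.approx(1.0)

    def test_signal_decreases_for_cation_adsorption(self):
        # negative bilayer + positive added charge -> monotone decrease
        c = np.logspace(-9, -2, 30)
        e = model_efield(c, 1.0, -3.8, 1.6e6, 0.54, 0.10, -0.1)
        assert np.all(np.diff(e) < 0)

    def test_charge_neutralized_plateau(self):
        p = GCParams()
        a, b, s0 = 1.0, -3.8, -0.1
        # theta -> 1 with dsigma = -sigma0: plateau at A/(A + B*Phi0)
        e_inf = model_efield(1e6, a, b, 1e9, 1.0, -s0, s0, p)
        assert e_inf == pytest.approx(a / (a + b * gc_potential(s0, p)), rel=1e-4)

    def test_ab_joint_rescaling_invariance(self):
        c = np.logspace(-8, -3, 8)
        e1 = model_efield(c, 1.0, -3.8, 1e6, 0.5, 0.1, -0.1)
        e2 = model_efield(c, 7.0, 7 * -3.8, 1e6, 0.5, 0.1, -0.1)
        assert e1 == pytest.approx(e2)

    def test_degenerate_normalization_rejected(self):
        phi0 = gc_potential(-0.1)
        with pytest.raises(DegenerateNormalizationError):
            model_efield(1e-6, 1.0, -1.0 / phi0, 1e6, 0.5, 0.1, -0.1)


class TestAugmentExtrapolatedPoint:
    def _iso(self):
        c = np.logspace(-8, -3, 6)
        e = np.array([1.0, 0.95, 0.9, 0.80, 0.82, 0.84])
        return IsothermData(c, e)

    def test_mean_of_last_three(self):
        out = augment_extrapolated_point(self._iso(), c_extrap=0.1, k=3)
        assert out.concentration[-1] == 0.1
        assert out.e_norm[-1] == pytest.approx(0.82)
        assert out.extrapolated[-1] and not out.extrapolated[:-1].any()

    def test_k_equal_one_copies_last_point(self):
        out = augment_extrapolated_point(self._iso(), k=1)
        assert out.e_norm[-1] == pytest.approx(0.84)

    def test_double_augmentation_rejected(self):
        out = augment_extrapolated_point(self._iso())
        with pytest.raises(ValueError):
            augment_extrapolated_point(out)

    def test_too_few_points(self):
        iso = IsothermData(np.array([1e-6, 1e-5]), np.array([1.0, 0.9]))
        with pytest.raises(InsufficientDataError):
            augment_extrapolated_point(iso, k=3)


class TestFitIsotherm:
    def test_noiseless_exact_recovery(self):
        spec = sim.default_scenario("ARG8", seed=3, noise_enorm=0.0)
        fit = fit_isotherm(sim.gen_isotherm(spec), spec.gc, sigma0=spec.sigma0)
        assert fit.residual_norm < 1e-8
        assert fit.k_ads == pytest.approx(spec.k_ads, rel=1e-4)
        assert fit.n == pytest.approx(spec.hill_n, rel=1e-4)
        assert fit.delta_sigma == pytest.approx(spec.delta_sigma, rel=1e-4)

    def test_calibrated_recovery_within_20pct(self):
        # 12 log-spaced concentrations, 1% multiplicative noise, fixed seed
        spec = sim.default_scenario(
            "ARG8", seed=7, k_ads=1.5e6, hill_n=0.5, delta_sigma=0.10
        )
        fit = fit_isotherm(
            sim.gen_isotherm(spec), spec.gc, sigma0=spec.sigma0, fix_b=spec.b_response
        )
        assert fit.k_ads == pytest.approx(spec.k_ads, rel=0.20)
        assert fit.n == pytest.approx(spec.hill_n, rel=0.20)
        assert fit.delta_sigma == pytest.approx(spec.delta_sigma, rel=0.20)

    def test_flat_isotherm_gives_zero_added_charge(self):
        spec = sim.default_scenario("ARG8", seed=2, delta_sigma=0.0, noise_enorm=0.0)
        iso = sim.gen_isotherm(spec)
        # with the response calibrated, no signal change means no added charge
        fit = fit_isotherm(iso, spec.gc, sigma0=spec.sigma0, fix_b=spec.b_response)
        assert abs(fit.delta_sigma) <= max(2 * fit.stderr["delta_sigma"], 1e-3)
        # with B free the flat curve is perfectly degenerate (B ~ 0 fits any
        # delta-sigma): the fit must still reproduce the flat response
        free = fit_isotherm(iso, spec.gc, sigma0=spec.sigma0)
        assert free.residual_norm == pytest.approx(0.0, abs=1e-8)
        assert abs(free.b * free.delta_sigma) <= 1e-6

    def test_with_and_without_extrapolation_agree_within_1sigma(self):
        spec = sim.default_scenario("ARG8", seed=11)
        iso = sim.gen_isotherm(spec)
        fa = fit_isotherm(augment_extrapolated_point(iso), spec.gc, sigma0=spec.sigma0)
        fb = fit_isotherm(iso, spec.gc, sigma0=spec.sigma0)
        for name in ("k_ads", "n", "delta_sigma"):
            diff = abs(getattr(fa, name) - getattr(fb, name))
            combined = math.hypot(fa.stderr[name], fb.stderr[name])
            assert diff <= combined

    def test_too_few_points_rejected(self):
        iso = IsothermData(np.logspace(-6, -4, 3), np.array([1.0, 0.9, 0.8]))
        with pytest.raises(InsufficientDataError):
            fit_isotherm(iso)

    def test_sklearn_estimator_interface(self):
        spec = sim.default_scenario("ARG8", seed=5, noise_enorm=0.0)
        iso = sim.gen_isotherm(spec)
        est = HillGouyChapmanIsotherm(sigma0=-0.1).fit(iso.concentration, iso.e_norm)
        pred = est.predict(iso.concentration)
        assert pred == pytest.approx(iso.e_norm, abs=1e-6)
        assert set(est.get_params()) >= {"sigma0", "fix_b", "n_starts", "random_state"}


class TestSensitivityScan:
    def _augmented(self, **kw):
        spec = sim.default_scenario("ARG8", seed=11, **kw)
        return spec, augment_extrapolated_point(sim.gen_isotherm(spec))

    def test_zero_perturbation_degenerate_range(self):
        spec, iso = self._augmented()
        scan = sensitivity_scan(iso, spec.gc, sigma0=spec.sigma0, perturbation=0.0)
        lo, hi = scan["delta_sigma"]
        assert lo == pytest.approx(hi)

    def test_central_fit_inside_range(self):
        spec, iso = self._augmented()
        scan = sensitivity_scan(iso, spec.gc, sigma0=spec.sigma0, perturbation=0.10)
        lo, hi = scan["delta_sigma"]
        central = scan["fits"]["central"].delta_sigma
        assert lo - 1e-12 <= central <= hi + 1e-12

    def test_range_width_grows_with_perturbation(self):
        spec, iso = self._augmented(noise_enorm=0.0)
        widths = []
        for pert in (0.02, 0.05, 0.10):
            scan = sensitivity_scan(
                iso, spec.gc, sigma0=spec.sigma0, perturbation=pert,
                fix_b=spec.b_response,
            )
            lo, hi = scan["delta_sigma"]
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_requires_extrapolated_point(self):
        spec = sim.default_scenario("ARG8", seed=1)
        with pytest.raises(ValueError):
            sensitivity_scan(sim.gen_isotherm(spec), spec.gc)


class TestFreeEnergyAndIonization:
    def test_table_free_energies(self):
        # the 55.5 M reference reproduces both printed Delta G values
        assert free_energy(1.6e6) == pytest.approx(-45.4, abs=0.1)
        assert free_energy(1.0e6) == pytest.approx(-44.2, abs=0.1)

    def test_reference_state_zero(self):
        assert free_energy(1.0 / 55.5) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "per_res, n, expected", [(-5.9, 8, -47.2), (-3.3, 1, -3.3), (-5.9, 9, -53.1)]
    )
    def test_additive_expectation(self, per_res, n, expected):
        assert additive_expectation(per_res, n) == pytest.approx(expected)

    def test_percent_ionization(self):
        assert percent_ionization(0.05, 0.05) == pytest.approx(100.0)
        assert percent_ionization(0.0, 0.05) == 0.0
        assert percent_ionization(0.08, 0.079) == pytest.approx(101.3, abs=0.1)
        with pytest.raises(ValueError):
            percent_ionization(0.05, 0.0)
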