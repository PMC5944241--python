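"""Charge-profile integration, Poisson potentials, Grahame fits, binding counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepcharge import simulate as sim
from pepcharge.constants import ANGSTROM, ELEMENTARY_CHARGE, EPSILON_0, K_B
from pepcharge.electrostatics import (
    ApparentDielectricFit,
    BindingGeometry,
    ChargeDensityProfile,
    bound_monomer_count,
    fit_apparent_dielectric,
    grahame_sigma,
    integrate_charge,
    minimum_image_distances,
    poisson_potential,
)
from pepcharge.exceptions import DegenerateFitError, NonUniformGridError
from pepcharge.isotherm import GCParams, gc_potential
from pepcharge.simulate import _gc_phi


def brute_force_counts(geom: BindingGeometry) -> dict:
    """Independent O(N*M) oracle: plain python loops, explicit min-image."""
    out = {int(p): 0 for p in np.unique(geom.peptide_id)}
    for i in range(len(geom.sidechain_xyz)):
        cut = geom.cutoffs[str(geom.sidechain_type[i])]
        best = math.inf
        for j in range(len(geom.phosphorus_xyz)):
            d2 = 0.0
            for k in range(3):
                dd = geom.sidechain_xyz[i][k] - geom.phosphorus_xyz[j][k]
                dd -= geom.box[k] * round(dd / geom.box[k])
                d2 += dd * dd
            best = min(best, math.sqrt(d2))
        if best <= cut:
            out[int(geom.peptide_id[i])] += 1
    return out


class TestIntegrateCharge:
    def test_zero_profile(self):
        z = np.arange(0, 10, 0.1)
        prof = ChargeDensityProfile(z, {"ions": np.zeros_like(z)})
        assert integrate_charge(prof, ("ions",)) == pytest.approx(np.zeros_like(z))

    def test_square_pulse_plateau(self):
        z = np.arange(0, 50, 0.1)
        rho = np.where((z >= 10) & (z <= 20), 1e8, 0.0)  # C/m^3
        prof = ChargeDensityProfile(z, {"x": rho})
        sigma = integrate_charge(prof, ("x",))
        expected = 1e8 * 10 * ANGSTROM  # q = rho * width
        assert sigma[-1] == pytest.approx(expected, rel=0.02)
        assert sigma[z < 5] == pytest.approx(0.0)

    def test_gc_counter_charge(self):
        prof = sim.gen_gc_profile(sigma0=-0.1)
        sigma_ions = integrate_charge(prof, ("ions",))
        assert sigma_ions[-1] == pytest.approx(0.1, rel=1e-6)

    def test_total_neutrality_by_construction(self):
        prof = sim.gen_gc_profile(sigma0=-0.1)
        total = integrate_charge(prof, ("total",))
        assert abs(total[-1]) <= 1e-9 * 0.1

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(NonUniformGridError):
            ChargeDensityProfile(np.array([0.0, 1.0, 3.0]), {"x": np.zeros(3)})


class TestPoissonPotential:
    def test_zero_profile(self):
        z = np.arange(0, 10, 0.1)
        prof = ChargeDensityProfile(z, {"x": np.zeros_like(z)})
        assert poisson_potential(prof, ("x",)).phi == pytest.approx(np.zeros_like(z))

    def test_parallel_plate_capacitor(self):
        # sheets +/- sigma_s separated by d: |dphi| = sigma_s d / eps0
        z = np.arange(0, 40, 0.01)
        sigma_s, z1, z2 = 0.05, 10.0, 20.0
        w = 0.2
        g1 = np.exp(-0.5 * ((z - z1) / w) ** 2)
        g2 = np.exp(-0.5 * ((z - z2) / w) ** 2)
        rho = sigma_s * (g1 / (np.trapezoid(g1, z) * ANGSTROM)
                         - g2 / (np.trapezoid(g2, z) * ANGSTROM))
        prof = ChargeDensityProfile(z, {"sheets": rho})
        pot = poisson_potential(prof, ("sheets",))
        dphi = pot.phi[np.argmin(np.abs(z - 19.0))] - pot.phi[np.argmin(np.abs(z - 11.0))]
        expected = sigma_s * (19.0 - 11.0) * ANGSTROM / EPSILON_0
        assert abs(dphi) == pytest.approx(expected, rel=0.01)

    def test_matches_analytic_gc_within_1pct(self):
        # vacuum-permittivity double integration vs closed-form GC, 0.1 A grid
        params = GCParams(303.15, 0.15, 78.2)
        prof = sim.gen_gc_profile(-0.1, 0.15, 303.15, 78.2, dz=0.1)
        pot = poisson_potential(prof, ("total",))
        phi0 = gc_potential(-0.1, params)
        kappa = math.sqrt(
            2 * params.ion_density * ELEMENTARY_CHARGE**2
            / (78.2 * EPSILON_0 * K_B * 303.15)
        ) * ANGSTROM
        ana = _gc_phi(prof.z, 20.0, phi0, kappa, params.thermal_voltage)
        m = prof.z >= 21.5
        assert np.max(np.abs(pot.phi[m] - ana[m])) <= 0.01 * abs(phi0)

    def test_superposition(self):
        z = np.arange(0, 30, 0.1)
        rng = np.random.default_rng(0)
        r1 = rng.normal(0, 1e6, len(z))
        r2 = rng.normal(0, 1e6, len(z))
        r1 -= np.trapezoid(r1, z) / np.trapezoid(np.ones_like(z), z)
        r2 -= np.trapezoid(r2, z) / np.trapezoid(np.ones_like(z), z)
        p1 = poisson_potential(ChargeDensityProfile(z, {"x": r1}), ("x",))
        p12 = poisson_potential(ChargeDensityProfile(z, {"x": r1 + r2}), ("x",))
        p2 = poisson_potential(ChargeDensityProfile(z, {"x": r2}), ("x",))
        assert p12.phi == pytest.approx(p1.phi + p2.phi, abs=1e-9)

    def test_non_neutral_selection_warns(self):
        z = np.arange(0, 10, 0.1)
        prof = ChargeDensityProfile(z, {"x": np.full_like(z, 1e6)})
        with pytest.warns(UserWarning, match="not neutral"):
            poisson_potential(prof, ("x",))


class TestGrahame:
    def test_zero_potential(self):
        assert grahame_sigma(0.0) == 0.0

    def test_inverse_of_gc_potential(self):
        p = GCParams(298.15, 0.1, 78.2)
        for sigma in (-0.2, -0.1, -1e-4, 3e-3, 0.15):
            phi = gc_potential(sigma, p)
            back = grahame_sigma(phi, 0.1, 298.15, 78.2)
            assert back == pytest.approx(sigma, rel=1e-12, abs=1e-18)

    def test_reference_inverse_value(self):
        assert grahame_sigma(-0.0883, 0.1, 298.15, 78.2) == pytest.approx(-0.0999, abs=5e-4)

    @given(sigma=st.floats(-0.5, 0.5), c=st.sampled_from([0.1, 0.15]))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_machine_precision(self, sigma, c):
        phi = gc_potential(sigma, GCParams(298.15, c, 78.2))
        assert grahame_sigma(phi, c, 298.15, 78.2) == pytest.approx(
            sigma, rel=1e-10, abs=1e-15
        )


class TestApparentDielectric:
    @pytest.mark.parametrize("eps_true", [10.0, 27.0, 78.0])
    @pytest.mark.parametrize("c,sigma0", [(0.15, -0.1), (0.1, -0.05)])
    def test_recovers_eps_true_within_5pct(self, eps_true, c, sigma0):
        prof = sim.gen_gc_profile(sigma0, c, 303.15, eps_true, dz=0.1)
        pot = poisson_potential(prof, ("total",))
        sigma = integrate_charge(prof, ("lipid", "ions"))
        fit = fit_apparent_dielectric(pot, sigma, (22.0, 26.0), c, 303.15)
        assert fit.epsilon_app == pytest.approx(eps_true, rel=0.05)

    def test_degenerate_zero_input_rejected(self):
        est = ApparentDielectricFit()
        with pytest.raises(DegenerateFitError):
            est.fit(np.zeros(5), np.zeros(5))

    def test_window_outside_grid_rejected(self):
        prof = sim.gen_gc_profile()
        pot = poisson_potential(prof, ("total",))
        sigma = integrate_charge(prof, ("lipid", "ions"))
        with pytest.raises(ValueError):
            fit_apparent_dielectric(pot, sigma, (900.0, 950.0))

    def test_estimator_predict(self):
        prof = sim.gen_gc_profile(epsilon_true=27.0)
        pot = poisson_potential(prof, ("total",))
        sigma = integrate_charge(prof, ("lipid", "ions"))
        m = (pot.z >= 22.0) & (pot.z <= 26.0)
        est = ApparentDielectricFit().fit(pot.phi[m], sigma[m])
        assert est.predict(pot.phi[m]) == pytest.approx(sigma[m], rel=0.05)


class TestBoundMonomerCount:
    def test_no_peptides(self):
        geom = BindingGeometry(
            np.zeros((0, 3)), np.array([]), np.array([], dtype=int),
            np.zeros((1, 3)), np.array([50.0, 50.0, 50.0]),
        )
        counts = bound_monomer_count(geom)
        assert counts.per_peptide == {} and counts.histogram.sum() == 0

    @pytest.mark.parametrize("dist,expected", [(5.5, 1), (5.6, 0)])
    def test_inclusive_boundary_convention(self, dist, expected):
        geom = BindingGeometry(
            np.array([[10.0 + dist, 10.0, 10.0]]), np.array(["ARG"]),
            np.array([0]), np.array([[10.0, 10.0, 10.0]]),
            np.array([60.0, 60.0, 60.0]),
        )
        assert bound_monomer_count(geom).per_peptide[0] == expected

    def test_minimum_image_wraps_box(self):
        d = minimum_image_distances(
            np.array([[1.0, 0.0, 0.0]]), np.array([[59.0, 0.0, 0.0]]),
            np.array([60.0, 60.0, 60.0]),
        )
        assert d[0, 0] == pytest.approx(2.0)

    def test_randomized_fixtures_match_brute_force(self):
        rng = np.random.default_rng(99)
        for trial in range(5):
            planted = rng.integers(0, 9, size=20)
            geom = sim.gen_binding_geometry(planted, seed=int(rng.integers(1 << 30)))
            counts = bound_monomer_count(geom)
            oracle = brute_force_counts(geom)
            assert counts.per_peptide == oracle
            assert [counts.per_peptide[i] for i in range(20)] == list(planted)

    def test_histogram_and_bound_peptides(self):
        geom = sim.gen_binding_geometry([3] * 10 + [5] * 10 + [0] * 2, seed=4)
        counts = bound_monomer_count(geom)
        assert counts.histogram[3] == 10 and counts.histogram[5] == 10
        assert counts.histogram[0] == 2
        assert counts.n_bound_peptides == 20

    def test_margin_zero_counts_boundary_as_bound(self):
        geom = sim.gen_binding_geometry([4], bound_margin=0.0, seed=1)
        assert bound_monomer_count(geom).per_peptide[0] == 4

    def test_unknown_residue_type_rejected(self):
        geom = BindingGeometry(
            np.array([[1.0, 1.0, 1.0]]), np.array(["HIS"]), np.array([0]),
            np.array([[0.0, 0.0, 0.0]]), np.array([60.0, 60.0, 60.0]),
        )
        with pytest.raises(KeyError):
            bound_monomer_count(geom)
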