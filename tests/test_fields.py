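"""Radial finite-volume solvers for the potential and immune concentration."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0

from tumoreq.fields import (
    FormFunction,
    ImmuneParameters,
    RadialGrid,
    effective_death_rate,
    solve_chemo_potential,
    solve_immune_concentration,
)


def nested_quadrature_potential(grid, K, sigma, refine=10):
    """Oracle: Phi(r) = -(1/K) int_0^r (1/s) int_0^s rho rhs(rho) drho ds."""
    fine = RadialGrid(grid.radius, refine * grid.n_cells)
    rhs = sigma(fine.centers)
    rhs = rhs - fine.disk_average(rhs)
    inner = np.cumsum(fine.centers * rhs * fine.dr)       # int_0^s rho rhs
    phi = -np.cumsum(inner / fine.centers * fine.dr) / K
    phi = phi - fine.disk_average(phi)
    return np.interp(grid.centers, fine.centers, phi)


class TestChemoPotential:
    def test_constant_signal_gives_zero_potential(self, radial_grid):
        # mean subtraction annihilates constants
        sigma = FormFunction(3.0, 1e6)      # flat over the unit disk
        phi = solve_chemo_potential(radial_grid, 0.01, sigma)
        assert np.max(np.abs(phi.values)) < 1e-12 * sigma.amplitude

    def test_gaussian_signal_matches_nested_quadrature(self, radial_grid,
                                                       sigma_form):
        K = 0.01
        phi = solve_chemo_potential(radial_grid, K, sigma_form)
        oracle = nested_quadrature_potential(radial_grid, K, sigma_form)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(phi.values - oracle)) < 5e-3 * scale

    def test_zero_mean_gauge(self, radial_grid, sigma_form):
        phi = solve_chemo_potential(radial_grid, 0.5, sigma_form)
        assert radial_grid.disk_average(phi.values) == pytest.approx(
            0.0, abs=1e-15 * max(1.0, np.max(np.abs(phi.values))))

    def test_potential_independent_of_mass(self, radial_grid, sigma_form,
                                           immune_params):
        # mu1 scales the drift downstream, not the potential itself
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        phi2 = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        assert np.array_equal(phi.values, phi2.values)

    def test_nonpositive_diffusion_rejected(self, radial_grid, sigma_form):
        with pytest.raises(ValueError):
            solve_chemo_potential(radial_grid, 0.0, sigma_form)


class TestImmuneConcentration:
    def test_zero_mass_gives_zero_concentration(self, radial_grid,
                                                immune_params, sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        C = solve_immune_concentration(radial_grid, immune_params, phi, 0.0)
        assert np.all(C.values == 0.0)

    def test_linearity_without_drift(self, radial_grid,
                                     immune_params_nodrift, sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params_nodrift.K,
                                    sigma_form)
        C1 = solve_immune_concentration(radial_grid, immune_params_nodrift,
                                        phi, 1.0)
        C3 = solve_immune_concentration(radial_grid, immune_params_nodrift,
                                        phi, 3.0)
        assert np.allclose(C3.values, 3.0 * C1.values, rtol=1e-13, atol=0)

    @pytest.mark.parametrize("m_cells", [100, 200, 400])
    def test_helmholtz_closed_form_without_drift(self, m_cells,
                                                 immune_params_nodrift,
                                                 sigma_form):
        # gamma C - D lap C = mu1 R on the unit disk, C(1) = 0:
        # C = (mu1 R / gamma) (1 - I0(kappa r)/I0(kappa)), kappa = sqrt(g/D)
        grid = RadialGrid(1.0, m_cells)
        p = immune_params_nodrift
        phi = solve_chemo_potential(grid, p.K, sigma_form)
        mu1 = 2.5e-4
        C = solve_immune_concentration(grid, p, phi, mu1)
        kappa = math.sqrt(p.gamma / p.D)
        exact = mu1 * p.R_influx / p.gamma * (
            1.0 - i0(kappa * grid.centers) / i0(kappa))
        err = np.max(np.abs(C.values - exact)) / np.max(exact)
        assert err < 3e-3
        if m_cells == 400:
            err100 = self._closed_form_error(100, p, sigma_form, mu1)
            # refinement by 4 must shrink the error at the nominal order
            assert err < err100 / 3.0

    @staticmethod
    def _closed_form_error(m_cells, p, sigma_form, mu1):
        grid = RadialGrid(1.0, m_cells)
        phi = solve_chemo_potential(grid, p.K, sigma_form)
        C = solve_immune_concentration(grid, p, phi, mu1)
        kappa = math.sqrt(p.gamma / p.D)
        exact = mu1 * p.R_influx / p.gamma * (
            1.0 - i0(kappa * grid.centers) / i0(kappa))
        return np.max(np.abs(C.values - exact)) / np.max(exact)

    def test_nonnegative_under_strong_drift(self, radial_grid, sigma_form):
        # upwinding preserves positivity even for advection-dominated runs
        p = ImmuneParameters(chi=8.64e6, D=8.64e-5, gamma=2e-2, K=1e-2,
                             R_influx=1.74e-7)
        phi = solve_chemo_potential(radial_grid, p.K, sigma_form)
        C = solve_immune_concentration(radial_grid, p, phi, 1e4)
        assert np.all(C.values >= 0.0)

    def test_death_rate_monotone_in_mass(self, radial_grid, immune_params,
                                         delta_form, sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        masses = np.logspace(-8, 2, 11)
        rates = [effective_death_rate(
            solve_immune_concentration(radial_grid, immune_params, phi, m),
            delta_form) for m in masses]
        assert np.all(np.diff(rates) > 0)


class TestEffectiveDeathRate:
    def test_zero_amplitude_gives_zero(self, radial_grid, immune_params,
                                       sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        C = solve_immune_concentration(radial_grid, immune_params, phi, 1e-4)
        assert effective_death_rate(C, FormFunction(0.0, 0.1)) == 0.0

    def test_linear_in_amplitude(self, radial_grid, immune_params,
                                 delta_form, sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        C = solve_immune_concentration(radial_grid, immune_params, phi, 1e-4)
        one = effective_death_rate(C, delta_form)
        ten = effective_death_rate(
            C, FormFunction(10 * delta_form.amplitude, delta_form.width))
        assert ten == pytest.approx(10 * one, rel=1e-13)

    def test_matches_refined_quadrature(self, delta_form):
        # smooth tabulated concentration against an adaptive-quadrature oracle
        from tumoreq.fields import ScalarField

        grid = RadialGrid(1.0, 1000)
        conc = 1.0 - grid.centers ** 2
        got = effective_death_rate(ScalarField(conc, grid), delta_form)
        oracle, _ = quad(
            lambda r: delta_form(r) * (1.0 - r * r) * 2 * math.pi * r,
            0.0, 1.0, epsabs=1e-14)
        assert got == pytest.approx(oracle, rel=1e-5)

    def test_grid_mismatch_rejected(self, radial_grid, delta_form,
                                    immune_params, sigma_form):
        phi = solve_chemo_potential(radial_grid, immune_params.K, sigma_form)
        C = solve_immune_concentration(radial_grid, immune_params, phi, 1e-4)
        with pytest.raises(ValueError):
            effective_death_rate(C, delta_form, RadialGrid(1.0, 50))
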