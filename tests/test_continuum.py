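"""Continuum layer: effective fields, steady state, master equation, MFPT."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from colloidjump.continuum import (
    ContinuumSolution,
    EffectiveFields,
    bin_masses,
    effective_fields,
    master_equation_propagate,
    mfpt,
    steady_state,
)
from colloidjump.profiles import Geometry, ParametricField, ProfileParams

from test_synthetic import homogeneous_field


class TestEffectiveFields:
    def test_homogeneous_field_has_no_gradient_term(self):
        geo = Geometry(half_width=50.0, colloid_radius=5.0)
        fld = homogeneous_field(lam=0.3, L=2.0, geometry=geo)
        grid = np.linspace(5, 50, 91)
        ef = effective_fields(fld, 0.05, grid)
        m2 = 2 * 2.0**2
        assert np.allclose(ef.D_eff, 0.05 + 0.3 * m2 / 2)
        assert np.allclose(ef.V_eff, 0.0, atol=1e-12)

    def test_bulk_limit_matches_closed_expression(self, table1):
        # profiles extrapolate smoothly past the half-width; far from the
        # wall D_eff -> D0 + lambda_b * L_b^2
        grid = np.linspace(5, 500, 991)
        ef = effective_fields(table1, 0.0439, grid)
        assert ef.D_eff[-1] == pytest.approx(0.0439 + 0.315 * 3.70**2, rel=1e-6)

    def test_numeric_and_analytic_derivatives_agree(self, table1):
        grid = np.linspace(5, 50, 901)
        a = effective_fields(table1, 0.0439, grid, derivative="analytic")
        n = effective_fields(table1, 0.0439, grid, derivative="numeric")
        interior = slice(2, -2)
        assert np.allclose(a.V_eff[interior], n.V_eff[interior], atol=2e-3)

    def test_symmetric_kernel_with_rising_activity_drifts_wallward(self):
        # m1 = 0 but lambda m2 increases with y: V_eff = -1/2 d(lambda m2)/dy < 0
        geo = Geometry(half_width=50.0, colloid_radius=5.0)
        fld = ParametricField(
            ProfileParams(L_bulk=3.0, l_plus=8.0, l_minus=8.0, lambda_wall=0.1, lambda_bulk=0.4, l_lambda=8.0, L_wall=3.0, y_col=5.0),
            geo,
        )
        grid = np.linspace(5, 40, 201)
        ef = effective_fields(fld, 0.05, grid)
        assert np.allclose(ef.lam_m1, 0.0, atol=1e-12)
        assert np.all(ef.V_eff[:-1] < 0)


class TestSteadyState:
    def _fields(self, grid, D, lam_m1):
        D = np.broadcast_to(np.asarray(D, float), grid.shape).copy()
        b = np.broadcast_to(np.asarray(lam_m1, float), grid.shape).copy()
        V = b - np.gradient(D, grid)
        return EffectiveFields(grid=grid, D_eff=D, V_eff=V, lam_m1=b, D0=float(D.min()))

    def test_uniform_when_no_drift_and_constant_diffusivity(self):
        grid = np.linspace(0, 10, 101)
        sol = steady_state(self._fields(grid, 2.0, 0.0))
        assert np.allclose(sol.P, 0.1, rtol=1e-9)

    def test_ito_form_when_only_diffusivity_varies(self):
        grid = np.linspace(0, 10, 2001)
        D = 1.0 + 0.5 * np.sin(grid / 3.0) ** 2
        sol = steady_state(self._fields(grid, D, 0.0))
        expected = (1.0 / D) / trapezoid(1.0 / D, grid)
        assert np.allclose(sol.P, expected, rtol=1e-6)

    def test_normalized_and_nonnegative(self, table1):
        grid = np.arange(5, 50 + 1e-9, 0.05)
        sol = steady_state(effective_fields(table1, 0.0439, grid))
        assert trapezoid(sol.P, grid) == pytest.approx(1.0, abs=1e-10)
        assert np.all(sol.P >= 0)

    def test_zero_flux_residual_on_fine_grid(self, table1):
        # stationary flux V_eff P - D_eff dP/dy vanishes relative to the
        # peak advective flux once the wall boundary layer is resolved
        grid = np.arange(5.0, 50.0 + 1e-9, 0.001)
        sol = steady_state(effective_fields(table1, 0.0439, grid))
        assert sol.flux_residual <= 1e-6

    def test_grid_convergence(self, table1):
        edges = np.linspace(5, 50, 46)
        sols = []
        for h in (0.05, 0.025):
            grid = np.arange(5, 50 + 1e-9, h)
            sols.append(bin_masses(steady_state(effective_fields(table1, 0.0439, grid)), edges))
        assert 0.5 * np.abs(sols[0] - sols[1]).sum() <= 1e-3

    def test_outward_drift_creates_the_depletion_minimum(self, table1):
        # with the fitted kernel asymmetry P has an interior local minimum;
        # forcing m1 = 0 (everything else kept) removes it
        grid = np.arange(5, 50 + 1e-9, 0.05)
        ef = effective_fields(table1, 0.0439, grid)
        sol = steady_state(ef)
        no_drift = EffectiveFields(
            grid=grid, D_eff=ef.D_eff, V_eff=ef.V_eff - ef.lam_m1, lam_m1=np.zeros_like(grid), D0=ef.D0
        )
        sol0 = steady_state(no_drift)

        def has_interior_min(P):
            i = np.argmin(P[5:-5]) + 5
            return P[i] < P[:i].max() - 1e-9 and P[i] < P[i:].max() - 1e-9

        assert has_interior_min(sol.P)
        assert not has_interior_min(sol0.P)


class TestMasterEquation:
    def test_heat_equation_limit_spreads_gaussian(self, table1):
        geo = table1.geometry
        from test_simulator import quiet_field

        fld = quiet_field(geo)
        h = 0.25
        grid = np.arange(5 + h / 2, 50, h)
        D0 = 0.0439
        P0 = np.exp(-((grid - 27.5) ** 2) / (2.0 * 1.5**2))
        t_tot = 100.0
        P = master_equation_propagate(fld, D0, P0, grid, dt=0.1, n_steps=int(t_tot / 0.1))
        var0 = 1.5**2
        mean = trapezoid(grid * P, grid)
        var = trapezoid((grid - mean) ** 2 * P, grid)
        assert var == pytest.approx(var0 + 2 * D0 * t_tot, rel=0.02)

    def test_mass_conserved_each_step(self, table1):
        h = 0.25
        grid = np.arange(5 + h / 2, 50, h)
        P, diag = master_equation_propagate(
            table1, 0.0439, np.ones_like(grid), grid, dt=0.1, n_steps=500, return_diagnostics=True
        )
        assert diag["max_step_mass_defect"] < 1e-12
        assert diag["final_mass"] == pytest.approx(1.0, abs=1e-12)

    def test_homogeneous_symmetric_kernel_relaxes_to_uniform(self):
        geo = Geometry(half_width=50.0, colloid_radius=5.0)
        fld = homogeneous_field(lam=0.3, L=2.0, geometry=geo)
        h = 0.5
        grid = np.arange(5 + h / 2, 50, h)
        P0 = np.exp(-((grid - 30.0) ** 2) / 8.0)
        P = master_equation_propagate(fld, 0.0439, P0, grid, dt=0.1, n_steps=20000)
        # the wall-stopping rule builds an accumulation zone ~2 jump
        # lengths wide at the boundary; beyond it the profile is flat
        interior = P[8:] * h
        assert interior.max() - interior.min() < 0.01 * interior.mean()

    def test_cfl_violation_rejected(self, table1):
        h = 0.05
        grid = np.arange(5 + h / 2, 50, h)
        with pytest.raises(ValueError):
            master_equation_propagate(table1, 0.5, np.ones_like(grid), grid, dt=0.1, n_steps=1)


class TestMFPT:
    def test_constant_coefficient_closed_form(self):
        W, D = 50.0, 2.0
        grid = np.linspace(0, W, 4001)
        ef = EffectiveFields(
            grid=grid,
            D_eff=np.full_like(grid, D),
            V_eff=np.zeros_like(grid),
            lam_m1=np.zeros_like(grid),
            D0=D,
        )
        for y in (10.0, 25.0, 50.0):
            exact = (2 * W * y - y**2) / (2 * D)
            assert mfpt(ef, y, absorbing="lower") == pytest.approx(exact, rel=1e-6)
        y_up = 20.0
        exact = (2 * W * (W - y_up) - (W - y_up) ** 2) / (2 * D)
        assert mfpt(ef, y_up, absorbing="upper") == pytest.approx(exact, rel=1e-6)

    def test_drift_toward_absorber_shortens_passage(self):
        grid = np.linspace(0, 50, 2001)
        base = dict(D_eff=np.full_like(grid, 2.0), V_eff=np.full_like(grid, -0.05), D0=2.0)
        drift = EffectiveFields(grid=grid, lam_m1=np.full_like(grid, -0.05), **base)
        still = EffectiveFields(
            grid=grid, D_eff=base["D_eff"], V_eff=np.zeros_like(grid), lam_m1=np.zeros_like(grid), D0=2.0
        )
        assert mfpt(drift, 25.0) < mfpt(still, 25.0)

    def test_monte_carlo_agreement_on_fitted_field(self, table1):
        # Euler-Maruyama sampling of the effective SDE (Ito drift lambda m1,
        # diffusivity D_eff) vs the quadrature solution, absorbing at the
        # wall offset and reflecting at 25 um
        grid = np.arange(5.0, 25.0 + 1e-9, 0.01)
        ef = effective_fields(table1, 0.0439, grid)
        start = 15.0
        T_pred = mfpt(ef, start, absorbing="lower")

        rng = np.random.default_rng(8)
        n, dt = 300, 0.01
        y = np.full(n, start)
        alive = np.ones(n, bool)
        tau = np.zeros(n)
        from colloidjump.profiles import kernel_moments

        for _ in range(400_000):
            if not alive.any():
                break
            idx = np.nonzero(alive)[0]
            yy = y[idx]
            lam = np.asarray(table1.lambda_at(yy))
            b = lam * np.asarray(kernel_moments(table1, yy, 1))
            D = 0.0439 + lam * np.asarray(kernel_moments(table1, yy, 2)) / 2
            yy = yy + b * dt + rng.normal(0, 1, idx.size) * np.sqrt(2 * D * dt)
            yy = np.where(yy > 25.0, 50.0 - yy, yy)
            y[idx] = yy
            tau[idx] += dt
            alive[idx[yy <= 5.0]] = False
        assert not alive.any()
        se = tau.std() / np.sqrt(n)
        assert abs(tau.mean() - T_pred) < 3 * se

    def test_degenerate_interval_rejected(self):
        grid = np.array([1.0, 1.0, 1.0])
        ef = EffectiveFields(grid=grid, D_eff=np.ones(3), V_eff=np.zeros(3), lam_m1=np.zeros(3), D0=1.0)
        with pytest.raises(ValueError):
            mfpt(ef, 1.0)
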