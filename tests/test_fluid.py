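"""Periodic Stokes solver and FENE-P constitutive model."""

import numpy as np
import pytest

from blebsim import fluid as fl
from blebsim.errors import ConstitutiveError, GeometryError, MomentumViolationError


@pytest.fixture()
def params():
    return fl.FluidParameters(grid_shape=(64, 64), domain_size=80.0)


class TestSolveStokes:
    def test_zero_force_gives_zero_flow(self, params):
        v, p = fl.solve_stokes(np.zeros((2, 64, 64)), None, params)
        assert np.all(v == 0.0)
        assert np.allclose(p, p.flat[0])

    @pytest.mark.parametrize("mode", [1, 3, 7])
    def test_single_fourier_mode_closed_form(self, params, mode):
        # F = (F0 sin(k y), 0)  ->  v_x = F0/(eta k^2) sin(k y)
        _, y = params.node_coords()
        k = 2 * np.pi * mode / params.domain_size
        F0 = 2.5
        f = np.zeros((2, 64, 64))
        f[0] = F0 * np.sin(k * y)
        v, p = fl.solve_stokes(f, None, params)
        exact = F0 / (params.eta_f * k**2) * np.sin(k * y)
        assert np.max(np.abs(v[0] - exact)) < 1e-6 * np.max(np.abs(exact))
        assert np.max(np.abs(v[1])) < 1e-12
        assert np.max(np.abs(p)) < 1e-12

    def test_velocity_is_divergence_free(self, params):
        rng = np.random.default_rng(7)
        f = rng.normal(size=(2, 64, 64))
        f -= f.mean(axis=(1, 2), keepdims=True)
        v, _ = fl.solve_stokes(f, None, params)
        g = fl.velocity_gradient(v, params)
        div = np.max(np.abs(fl.divergence(v, params)))
        assert div < 1e-8 * np.max(np.abs(g))

    def test_mean_velocity_and_pressure_are_zero(self, params):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(2, 64, 64))
        f -= f.mean(axis=(1, 2), keepdims=True)
        v, p = fl.solve_stokes(f, None, params)
        assert abs(v.mean()) < 1e-12
        assert abs(p.mean()) < 1e-12

    def test_net_force_raises_momentum_error(self, params):
        f = np.ones((2, 64, 64))
        with pytest.raises(MomentumViolationError):
            fl.solve_stokes(f, None, params)


class TestConformation:
    def test_fene_equilibrium_is_stationary(self, params):
        state = fl.FluidState(params)
        before = state.conformation.copy()
        fl.evolve_conformation(state, 1e-2)
        assert np.allclose(state.conformation, before, atol=1e-14)

    def test_oldroyd_b_identity_is_stationary(self):
        p = fl.FluidParameters(grid_shape=(16, 16), L_p=1e6)
        state = fl.FluidState(p)
        state.conformation[:2] = 1.0
        state.conformation[2] = 0.0
        before = state.conformation.copy()
        fl.evolve_conformation(state, 1e-2)
        assert np.allclose(state.conformation, before, atol=1e-9)

    def test_relaxation_is_monotone_toward_equilibrium(self, params):
        state = fl.FluidState(params)
        state.relaxation_time[:] = 1.0
        state.conformation[0] = 3.0
        state.conformation[1] = 0.5
        state.conformation[2] = 0.4
        keq = fl.fene_equilibrium(params.L_p)
        target = np.zeros_like(state.conformation)
        target[0] = keq
        target[1] = keq

        def dist():
            d = state.conformation - target
            return float(np.sqrt(d[0] ** 2 + d[1] ** 2 + 2 * d[2] ** 2).max())

        last = dist()
        for _ in range(50):
            fl.evolve_conformation(state, 0.5)
            now = dist()
            assert now <= last + 1e-12
            last = now
        assert last < 1e-3

    def test_oldroyd_b_shear_steady_state(self):
        # dvx/dy = gd, L_p -> inf: kxy = lam*gd, kxx = 1 + 2 (lam gd)^2
        p = fl.FluidParameters(grid_shape=(8, 8), L_p=1e6,
                               lambda_p_in=2.0, lambda_p_out=2.0,
                               domain_size=2 * np.pi)
        state = fl.FluidState(p)
        gd = 0.3
        G = np.zeros((2, 2, 8, 8))
        G[0, 1] = gd
        orig = fl.velocity_gradient
        fl.velocity_gradient = lambda v, pp: G
        try:
            for _ in range(20000):
                fl.evolve_conformation(state, 5e-3)
        finally:
            fl.velocity_gradient = orig
        lam = 2.0
        assert state.conformation[2][0, 0] == pytest.approx(lam * gd, rel=1e-4)
        assert state.conformation[0][0, 0] == pytest.approx(
            1 + 2 * (lam * gd) ** 2, rel=1e-4)
        assert state.conformation[1][0, 0] == pytest.approx(1.0, rel=1e-4)

    def test_one_step_matches_oldroyd_b_at_large_extensibility(self):
        # with L_p >= 1e4 a step must agree with the L_p -> infinity update
        p_fene = fl.FluidParameters(grid_shape=(16, 16), L_p=1e4,
                                    domain_size=2 * np.pi)
        s = fl.FluidState(p_fene)
        rng = np.random.default_rng(0)
        s.conformation[0] = 1.0 + 0.3 * rng.random((16, 16))
        s.conformation[1] = 1.0 + 0.3 * rng.random((16, 16))
        s.conformation[2] = 0.1 * rng.random((16, 16))
        k0 = s.conformation.copy()
        lam = s.relaxation_time
        dt = 1e-2
        fl.evolve_conformation(s, dt)
        # analytic Oldroyd-B relaxation step (v = 0): k += dt*(I - k)/lam
        expect = k0.copy()
        expect[0] += dt * (1 - k0[0]) / lam
        expect[1] += dt * (1 - k0[1]) / lam
        expect[2] += dt * (0 - k0[2]) / lam
        err = np.max(np.abs(s.conformation - expect)) / np.max(np.abs(expect))
        assert err < 1e-4

    def test_fene_bound_violation_raises(self, params):
        state = fl.FluidState(params)
        state.conformation[0] = params.L_p**2
        with pytest.raises(ConstitutiveError):
            fl.polymer_stress(state)


class TestPolymerStress:
    def test_equilibrium_stress_is_zero(self, params):
        state = fl.FluidState(params)
        s = fl.polymer_stress(state)
        assert np.max(np.abs(s)) < 1e-12

    def test_zero_polymer_viscosity_gives_zero_stress(self, params):
        state = fl.FluidState(params)
        state.conformation[0] = 2.0
        state.polymer_viscosity[:] = 0.0
        assert np.max(np.abs(fl.polymer_stress(state))) == 0.0

    def test_hand_evaluated_point(self):
        # kappa = diag(2, 1), L^2 = 100, eta/lam = 0.01
        p = fl.FluidParameters(grid_shape=(4, 4), L_p=10.0)
        state = fl.FluidState(p)
        state.conformation[0] = 2.0
        state.conformation[1] = 1.0
        state.conformation[2] = 0.0
        state.polymer_viscosity[:] = 0.01
        state.relaxation_time[:] = 1.0
        s = fl.polymer_stress(state)
        assert s[0].flat[0] == pytest.approx(0.01 * (2 / 0.97 - 1))
        assert s[1].flat[0] == pytest.approx(0.01 * (1 / 0.97 - 1))
        assert np.all(s[2] == 0.0)


class TestMaterialFields:
    def test_indicator_sharp_far_from_interface(self, params):
        from blebsim.structures import circle_nodes

        R = 10.0
        p = fl.FluidParameters(grid_shape=(64, 64), domain_size=80.0,
                               eta_p_in=1.0, eta_p_out=0.0)
        poly = circle_nodes(128, R, (40.0, 40.0))
        eta, lam = fl.assign_material_fields(poly, p)
        gx, gy = p.node_coords()
        r = np.hypot(gx - 40.0, gy - 40.0)
        h = p.h
        assert np.allclose(eta[r < R - 2 * h], 1.0)
        assert np.allclose(eta[r > R + 2 * h], 0.0)

    def test_uniform_when_inside_equals_outside(self, params):
        from blebsim.structures import circle_nodes

        poly = circle_nodes(64, 10.0, (40.0, 40.0))
        eta, lam = fl.assign_material_fields(
            poly, fl.FluidParameters(grid_shape=(64, 64), domain_size=80.0,
                                     eta_p_in=2.0, eta_p_out=2.0,
                                     lambda_p_in=5.0, lambda_p_out=5.0))
        assert np.all(eta == 2.0)
        assert np.all(lam == 5.0)

    def test_disk_area_quadrature(self):
        # integral of the inside indicator ~ pi R^2 within 2% at h = R/32
        from blebsim.structures import circle_nodes

        R = 10.0
        n = 64
        L = R * n / 32.0   # gives h = R/32 on an n-cell grid? h = L/n = R*...
        p = fl.FluidParameters(grid_shape=(128, 128), domain_size=40.0,
                               eta_p_in=1.0, eta_p_out=0.0)
        assert p.h == pytest.approx(R / 32.0)
        poly = circle_nodes(256, R, (20.0, 20.0))
        eta, _ = fl.assign_material_fields(poly, p)
        area = float(eta.sum()) * p.h**2
        assert area == pytest.approx(np.pi * R**2, rel=0.02)

    def test_self_intersecting_polygon_rejected(self, params):
        bowtie = np.array([[10.0, 10.0], [30.0, 30.0], [30.0, 10.0],
                           [10.0, 30.0]])
        with pytest.raises(GeometryError):
            fl.assign_material_fields(bowtie, params)
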