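import numpy as np
import pytest

from growdom import (
    DomainSpec,
    GrowthLaw,
    KernelSpec,
    ModelParams,
    PackingForm,
    ReferenceGrid,
    RhsAssembler,
    SchemeConfig,
    SemiDiscreteState,
    advective_interface_flux,
    apply_nonlocal,
    build_weights,
    diffusive_interface_flux,
    packing,
    proliferation,
)


def fixed_domain(L0=2.0, T=10.0):
    return DomainSpec(growth=GrowthLaw(kind="fixed", L0=L0), placement="L", T=T)


class TestDiffusiveFlux:
    def test_constant_field_zero_flux(self, grid256):
        f = diffusive_interface_flux(np.full(256, 2.2), grid256, D=1e-3, L=2.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-16)

    def test_linear_window_constant_flux(self):
        grid = ReferenceGrid(64)
        u = 3.0 * grid.centers  # linear; wraps only at the boundary
        f = diffusive_interface_flux(u, grid, D=0.5, L=2.0)
        np.testing.assert_allclose(f[:-1], -(0.5 / 2.0) * 3.0, rtol=1e-12)

    def test_zero_diffusion(self, grid256, rng):
        f = diffusive_interface_flux(rng.random(256), grid256, D=0.0, L=1.0)
        assert np.all(f == 0.0)


class TestAdvectiveFlux:
    @pytest.fixture
    def params(self):
        return ModelParams(D=0.0, omega=1.0, rho=0.0, U=1.0,
                           packing=PackingForm("clipped", P=0.8),
                           kernel=KernelSpec(xi=0.1, mu=1.0))

    @pytest.mark.parametrize("limiter", ["none_first_order", "van_leer"])
    def test_zero_velocity_zero_flux(self, params, rng, limiter):
        u = rng.random(64)
        f = advective_interface_flux(u, np.zeros(64), params,
                                     SchemeConfig(limiter=limiter))
        assert np.all(f == 0.0)

    def test_no_mass_out_of_empty_upwind_cell(self, params):
        u = np.zeros(32)
        u[10] = 0.5  # mass only in cell 10
        a = np.zeros(32)
        a[20] = 1.0  # rightward velocity at interface 20, upwind cell 20 empty
        f = advective_interface_flux(u, a, params,
                                     SchemeConfig(limiter="none_first_order"))
        assert f[20] == 0.0

    @pytest.mark.parametrize("limiter", ["none_first_order", "van_leer"])
    def test_flux_divergence_telescopes(self, params, rng, limiter):
        u = rng.random(128)
        a = rng.standard_normal(128)
        f = advective_interface_flux(u, a, params, SchemeConfig(limiter=limiter))
        div = f - np.roll(f, 1)
        assert abs(np.sum(div)) <= 1e-13 * np.max(np.abs(f))

    def test_first_order_is_upwind_sampling(self, params, rng):
        u = rng.random(64)
        a = rng.standard_normal(64)
        n = u * packing(u, params.packing)
        f = advective_interface_flux(u, a, params,
                                     SchemeConfig(limiter="none_first_order"))
        expected = np.where(a > 0, a * n, a * np.roll(n, -1))
        np.testing.assert_allclose(f, expected, rtol=1e-14)


class TestRhs:
    @pytest.fixture
    def params(self):
        return ModelParams(D=1e-3, omega=1.0, rho=0.0, U=1.0,
                           packing=PackingForm("clipped", P=0.8),
                           kernel=KernelSpec(xi=0.4, mu=1.2))

    def test_homogeneous_steady_state_fixed_domain(self, params, grid256):
        rhs = RhsAssembler(fixed_domain(), params, grid256)
        du = rhs(1.0, np.full(256, 0.8 / 3))
        np.testing.assert_allclose(du, 0.0, atol=1e-13)

    def test_growing_domain_pure_dilution(self, params, grid256):
        dom = DomainSpec(growth=GrowthLaw(kind="exponential", L0=2.0, alpha=0.1),
                         placement="L", T=10.0)
        rhs = RhsAssembler(dom, params, grid256)
        c = 0.2
        du = rhs(3.0, np.full(256, c))
        np.testing.assert_allclose(du, -0.1 * c, rtol=1e-12)

    @pytest.mark.parametrize("alpha,rho", [(0.0, 0.0), (0.1, 0.0), (0.1, 0.3)])
    def test_semidiscrete_mass_identity(self, alpha, rho, grid256, rng):
        # d/dt [L h sum(u)] = L h sum(rho u (1 - u/U)) exactly
        dom = DomainSpec(growth=GrowthLaw(kind="exponential", L0=2.0, alpha=alpha),
                         placement="L", T=10.0)
        params = ModelParams(D=1e-3, omega=1.0, rho=rho, U=1.0,
                             packing=PackingForm("clipped", P=0.8),
                             kernel=KernelSpec(xi=0.4, mu=1.2))
        rhs = RhsAssembler(dom, params, grid256)
        t = 2.5
        u = rng.random(256)
        du = rhs(t, u)
        L = dom.length(t)
        Ldot = dom.length_rate(t)
        h = grid256.h
        dm_dt = Ldot * h * np.sum(u) + L * h * np.sum(du)
        expected = L * h * np.sum(proliferation(u, params))
        scale = max(1.0, abs(L * h * np.sum(np.abs(du))))
        assert dm_dt == pytest.approx(expected, abs=1e-12 * scale)

    def test_weight_cache_invalidation(self, params, grid256):
        dom = DomainSpec(growth=GrowthLaw(kind="exponential", L0=2.0, alpha=0.1),
                         placement="L", T=10.0)
        rhs = RhsAssembler(dom, params, grid256)
        u = np.full(256, 0.2)
        rhs(1.0, u)
        n1 = rhs.n_weight_rebuilds
        rhs(1.0, u)  # same time, same L: cached
        assert rhs.n_weight_rebuilds == n1
        rhs(1.0 + 1e-6, u)  # L changed: rebuild
        assert rhs.n_weight_rebuilds == n1 + 1

    def test_placement_equivariance(self, params):
        # identical internal fields evolve identically on Type L and Type S
        grid = ReferenceGrid(128)
        rng = np.random.default_rng(5)
        u = 0.2 + 0.05 * rng.random(128)
        for alpha in (0.0, 0.05):
            domL = DomainSpec(growth=GrowthLaw(kind="exponential", L0=2.0,
                                               alpha=alpha), placement="L", T=5.0)
            domS = DomainSpec(growth=GrowthLaw(kind="exponential", L0=2.0,
                                               alpha=alpha), placement="S", T=5.0)
            duL = RhsAssembler(domL, params, grid)(1.0, u)
            duS = RhsAssembler(domS, params, grid)(1.0, u)
            np.testing.assert_array_equal(duL, duS)

    def test_state_rejects_non_finite(self):
        with pytest.raises(ValueError):
            SemiDiscreteState(t=0.0, u_hat=np.array([1.0, np.nan]))


class TestPositivity:
    def test_explicit_euler_below_cfl_stays_nonnegative(self):
        # first-order scheme, rho=0: upwind advection + central diffusion
        # keep cell averages non-negative under a CFL-limited Euler step
        grid = ReferenceGrid(100)
        params = ModelParams(D=1e-3, omega=1.0, rho=0.0, U=1.0,
                             packing=PackingForm("clipped", P=0.8),
                             kernel=KernelSpec(xi=0.1, mu=1.5))
        dom = fixed_domain(L0=1.0, T=10.0)
        rhs = RhsAssembler(dom, params, grid,
                           SchemeConfig(limiter="none_first_order"))
        rng = np.random.default_rng(11)
        L, h = 1.0, grid.h
        for _ in range(10):
            u = rng.uniform(0.0, 0.8, size=100)
            for _ in range(40):
                w = build_weights(grid, params.kernel, L)
                a = params.omega * apply_nonlocal(w, u)
                dt = 0.4 / (2 * params.D / (L * h) ** 2
                            + 2 * np.max(np.abs(a)) / (L * h) + 1e-30)
                u = u + dt * rhs(0.0, u)
                assert np.min(u) >= -1e-14


class TestSpatialConvergence:
    def test_diffusion_second_order(self):
        # periodic heat equation: u = sin(2 pi xhat) exp(-D (2 pi / L)^2 t)
        from scipy.integrate import solve_ivp

        D, L, T = 1e-2, 2.0, 2.0
        dom = fixed_domain(L0=L, T=T)
        errs = []
        for N in (32, 64, 128):
            grid = ReferenceGrid(N)
            params = ModelParams(D=D, omega=0.0, rho=0.0, U=1.0,
                                 kernel=KernelSpec(xi=0.2, mu=0.0))
            rhs = RhsAssembler(dom, params, grid)
            j = np.arange(N)
            h = grid.h
            u0 = (np.cos(2 * np.pi * j * h) - np.cos(2 * np.pi * (j + 1) * h)) \
                / (2 * np.pi * h)
            sol = solve_ivp(rhs, (0, T), u0, method="DOP853",
                            rtol=1e-11, atol=1e-12)
            decay = np.exp(-D * (2 * np.pi / L) ** 2 * T)
            errs.append(np.max(np.abs(sol.y[:, -1] - u0 * decay)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.9)

    @pytest.mark.parametrize("limiter,min_order", [
        ("none_first_order", 1.0), ("van_leer", 1.5),
    ])
    def test_advection_dominated_order(self, limiter, min_order):
        # smooth aggregation-type profile, error against a fine-grid reference
        from scipy.integrate import solve_ivp

        T = 0.4
        dom = fixed_domain(L0=2.0, T=T)
        params = ModelParams(D=1e-5, omega=1.0, rho=0.0, U=1.0,
                             packing=PackingForm("clipped", P=0.8),
                             kernel=KernelSpec(xi=0.4, mu=1.2))

        def final_state(N):
            grid = ReferenceGrid(N)
            rhs = RhsAssembler(dom, params, grid, SchemeConfig(limiter=limiter))
            x = grid.centers
            u0 = 0.25 + 0.1 * np.sin(2 * np.pi * x) + 0.05 * np.cos(4 * np.pi * x)
            sol = solve_ivp(rhs, (0, T), u0, method="DOP853",
                            rtol=1e-10, atol=1e-11)
            return sol.y[:, -1]

        ref = final_state(1024)
        errs = []
        for N in (64, 128, 256):
            u = final_state(N)
            coarse_ref = ref.reshape(N, -1).mean(axis=1)
            errs.append(np.mean(np.abs(u - coarse_ref)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert orders[-1] >= min_order
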