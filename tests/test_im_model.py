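import numpy as np
import pytest
from scipy.integrate import solve_ivp

from imtracer.im_model import (
    IMParams,
    StartState,
    build_generator,
    cumulative_migration,
    im_density,
    im_implied_coalrates,
    im_survival,
)
from imtracer.msmc_density import msmc_tmrca_density
from imtracer.timegrid import make_time_grid


def _const_params(grid, N1=20_000.0, N2=20_000.0, m=0.0):
    n = grid.n_segments
    return IMParams(grid=grid, N1=np.full(n, N1), N2=np.full(n, N2),
                    m=np.full(n, m))


class TestGenerator:
    def test_rows_sum_to_zero(self, rng):
        for _ in range(10):
            Q = build_generator(rng.uniform(0, 1e-3), rng.uniform(1e2, 1e6),
                                rng.uniform(1e2, 1e6))
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-18)

    def test_isolated_islands(self):
        Q = build_generator(0.0, 10_000.0, 20_000.0)
        assert np.all(Q[1] == 0.0)  # S12 row: lineages can never meet
        assert Q[0, 1] == 0.0 and Q[2, 1] == 0.0

    def test_absorbing_coalesced_state(self):
        Q = build_generator(1e-4, 10_000.0, 20_000.0)
        np.testing.assert_array_equal(Q[3], 0.0)

    def test_matches_ode_integration(self):
        # matrix-exponential occupancy vs direct integration of dP/dt = P Q
        Q = build_generator(1e-4, 10_000.0, 10_000.0)
        t_end = 30_000.0
        from scipy.linalg import expm

        P_expm = expm(Q * t_end)
        for start in range(3):
            sol = solve_ivp(lambda t, p: p @ Q, (0, t_end),
                            np.eye(4)[start], rtol=1e-11, atol=1e-14,
                            dense_output=True)
            np.testing.assert_allclose(sol.y[:, -1], P_expm[start],
                                       atol=1e-8)


class TestDensity:
    def test_zero_migration_cross_density_is_zero(self, analysis_grid):
        params = _const_params(analysis_grid)
        t = np.linspace(0, 2e5, 40)
        np.testing.assert_array_equal(
            im_density(params, StartState.S12, t), 0.0)

    def test_single_population_exponential(self, analysis_grid):
        N = 20_000.0
        params = _const_params(analysis_grid, N1=N)
        t = np.array([0.0, 1e3, 1e4, 1e5])
        expected = np.exp(-t / (2 * N)) / (2 * N)
        np.testing.assert_allclose(
            im_density(params, StartState.S11, t), expected, rtol=1e-10)

    def test_island_symmetry(self, analysis_grid, rng):
        n = analysis_grid.n_segments
        params = IMParams(grid=analysis_grid,
                          N1=rng.uniform(5e3, 5e4, n),
                          N2=np.empty(n), m=rng.uniform(0, 1e-4, n))
        object.__setattr__(params, "N2", params.N1.copy())
        t = np.linspace(0, 3e5, 25)
        np.testing.assert_allclose(
            im_density(params, StartState.S11, t),
            im_density(params, StartState.S22, t), rtol=1e-12)

    def test_density_matches_ctmc_simulation(self, coarse_grid, rng):
        # Monte-Carlo oracle: Gillespie simulation of the 4-state chain,
        # archaic-free symmetric model; survival compared within 3 SE at
        # 10 time points
        N, m = 10_000.0, 1e-4
        params = _const_params(coarse_grid, N1=N, N2=N, m=m)
        n_rep = 100_000
        coal = 1.0 / (2.0 * N)
        state = np.ones(n_rep, dtype=int)  # 0=S11, 1=S12, 2=S22; start S12
        t = np.zeros(n_rep)
        coal_time = np.full(n_rep, np.inf)
        alive = np.ones(n_rep, bool)
        for _ in range(500):
            if not alive.any():
                break
            c = np.where(state == 1, 0.0, coal)
            tot = 2 * m + c
            t = t + np.where(alive, rng.exponential(1.0, n_rep) / tot, 0.0)
            coalesces = alive & (rng.random(n_rep) < c / tot)
            coal_time[coalesces] = t[coalesces]
            alive &= ~coalesces
            goes_left = rng.random(n_rep) < 0.5
            new_state = np.where(state == 1, np.where(goes_left, 0, 2), 1)
            state = np.where(alive, new_state, state)
        assert not alive.any()
        check_t = np.linspace(5e3, 2e5, 10)
        surv_model = im_survival(params, StartState.S12, check_t)
        for tt, sm in zip(check_t, surv_model):
            emp = np.mean(coal_time > tt)
            se = max(np.sqrt(sm * (1 - sm) / n_rep), 1e-6)
            assert abs(emp - sm) < 3 * se + 2e-3

    def test_density_normalizes_with_positive_migration(self, analysis_grid):
        params = _const_params(analysis_grid, N1=15_000.0, N2=25_000.0,
                               m=5e-5)
        bounds = analysis_grid.segment_boundaries_gens
        # integrate finely over the finite grid, then add the survival mass
        # (all of which eventually coalesces since m > 0 everywhere)
        for s0 in StartState:
            total = 0.0
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                t = np.linspace(lo, hi, 400)
                total += np.trapezoid(im_density(params, s0, t), t)
            total += im_survival(params, s0, [bounds[-1]])[0]
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_survival_nonincreasing(self, analysis_grid, rng):
        n = analysis_grid.n_segments
        params = IMParams(grid=analysis_grid, N1=rng.uniform(1e3, 1e5, n),
                          N2=rng.uniform(1e3, 1e5, n),
                          m=rng.uniform(0, 1e-4, n))
        t = np.linspace(0, 5e5, 100)
        for s0 in StartState:
            s = im_survival(params, s0, t)
            assert np.all(np.diff(s) <= 1e-12)


class TestCumulativeMigration:
    def test_zero_migration(self, analysis_grid):
        params = _const_params(analysis_grid)
        np.testing.assert_array_equal(
            cumulative_migration(params, [0.0, 1e4, 1e5]), 0.0)

    def test_single_segment_closed_form(self, coarse_grid):
        # pair-mixing convention: M = 1 - exp(-2 m t)
        m = 1e-4
        params = _const_params(coarse_grid, m=m)
        t = 5_000.0
        assert cumulative_migration(params, [t])[0] == pytest.approx(
            1.0 - np.exp(-2 * m * t), rel=1e-12)

    def test_doubling_m_squares_survival(self, analysis_grid, rng):
        n = analysis_grid.n_segments
        m = rng.uniform(0, 1e-4, n)
        p1 = IMParams(grid=analysis_grid, N1=np.full(n, 2e4),
                      N2=np.full(n, 2e4), m=m)
        p2 = IMParams(grid=analysis_grid, N1=np.full(n, 2e4),
                      N2=np.full(n, 2e4), m=2 * m)
        t = np.linspace(0, 4e5, 30)
        M1 = cumulative_migration(p1, t)
        M2 = cumulative_migration(p2, t)
        np.testing.assert_allclose(M2, 1 - (1 - M1) ** 2, rtol=1e-10)

    def test_monotone_and_bounded(self, analysis_grid, rng):
        n = analysis_grid.n_segments
        params = IMParams(grid=analysis_grid, N1=np.full(n, 2e4),
                          N2=np.full(n, 2e4), m=rng.uniform(0, 1e-3, n))
        t = np.linspace(0, 1e6, 200)
        M = cumulative_migration(params, t)
        assert M[0] == 0.0
        assert np.all(np.diff(M) >= 0)
        # mathematically M < 1; exp underflow may saturate to 1.0 exactly
        assert np.all((M >= 0) & (M <= 1))


class TestImpliedRates:
    def test_isolated_constant_hazard(self, analysis_grid):
        N = 20_000.0
        params = _const_params(analysis_grid, N1=N, N2=N)
        tab = im_implied_coalrates(params)
        lam = tab.lambdas * analysis_grid.mu
        np.testing.assert_allclose(lam[:, 0], 1 / (2 * N), rtol=1e-9)
        np.testing.assert_allclose(lam[:, 1], 0.0, atol=1e-15)

    def test_hazard_density_inverse_pair(self, analysis_grid):
        # densities rebuilt from the implied step rates converge to the IM
        # densities; at 64-fold refinement the midpoint comparison is
        # accurate to 1e-6 relative
        n = analysis_grid.n_segments
        params = IMParams(grid=analysis_grid,
                          N1=np.full(n, 15_000.0), N2=np.full(n, 30_000.0),
                          m=np.full(n, 4e-5))
        tab = im_implied_coalrates(params, refine=64)
        mu = analysis_grid.mu
        mids = 0.5 * (tab.left_boundaries + tab.right_boundaries)[:-1] / mu
        # the cross density vanishes at the origin, where a relative
        # criterion is degenerate; compare beyond the first segment
        keep_t = mids > analysis_grid.segment_boundaries_gens[1]
        for s0 in StartState:
            rebuilt = msmc_tmrca_density(tab, s0, mids, mu)
            direct = im_density(params, s0, mids)
            keep = (direct > 1e-30) & keep_t
            np.testing.assert_allclose(rebuilt[keep], direct[keep],
                                       rtol=1e-6)
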