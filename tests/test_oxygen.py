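import numpy as np
import pytest
from scipy.integrate import solve_ivp

import vascrad as vr
from vascrad.oxygen import (StabilityError, _neighbour_sum, build_consumption,
                            relax_to_quasi_steady, step_oxygen, uptake_rate)
from vascrad.state import TissueState
from vascrad.vessels import VesselPattern


def make_state(N, coords, fill="empty", c0=1.0):
    pattern = VesselPattern(N=N, coords=np.asarray(coords).reshape(-1, 2)
                            if len(coords) else np.empty((0, 2)))
    return TissueState.from_pattern(pattern, fill=fill, c0=c0)


class TestUptake:
    def test_half_maximal_at_michaelis_constant(self, params):
        rate = uptake_rate(params.K_m, 1.0, params)
        assert rate == pytest.approx(params.r_c / 2, rel=1e-12)
        assert rate == pytest.approx(25.77, abs=0.02)

    def test_zero_at_zero_oxygen(self, params):
        assert uptake_rate(0.0, 1.0, params) == 0.0

    def test_tumour_rate_near_saturation(self, params):
        rate = uptake_rate(1.0, 2.0, params)
        assert rate == pytest.approx(2 * params.r_c / 1.01, rel=1e-12)
        assert rate == pytest.approx(102.07, abs=0.05)

    def test_negative_oxygen_rejected(self, params):
        with pytest.raises(ValueError):
            uptake_rate(-0.1, 1.0, params)


class TestExplicitStep:
    def test_uniform_field_without_sources_or_sinks_is_invariant(self, params):
        state = make_state(9, [], c0=0.4)
        m = build_consumption(state, params)
        change = step_oxygen(state, m, params)
        assert change == 0.0
        assert np.all(state.oxygen == 0.4)

    def test_single_vessel_drives_field_monotonically_to_one(self, params):
        state = make_state(9, [[4, 4]], c0=0.2)
        m = build_consumption(state, params)
        prev = state.oxygen.copy()
        for _ in range(500):
            step_oxygen(state, m, params)
            assert np.all(state.oxygen >= prev - 1e-14)
            prev = state.oxygen.copy()
        assert state.oxygen.min() > 0.2

    def test_uniform_consumers_match_scalar_ode(self, params):
        """With no vessels, uniform cells decay identically at every site;
        compare against a high-accuracy scalar quadrature of
        dc/dt = -r_c c/(c + K_m)."""
        state = make_state(7, [], fill="healthy", c0=1.0)
        m = build_consumption(state, params)
        n_steps = 3000  # c stays O(0.1): within first-order step accuracy
        for _ in range(n_steps):
            step_oxygen(state, m, params)
        t_end = n_steps * params.dt_oxygen_nd
        sol = solve_ivp(
            lambda t, c: -params.r_c * c / (c + params.K_m),
            (0, t_end), [1.0], rtol=1e-10, atol=1e-12)
        assert np.ptp(state.oxygen) < 1e-12  # stays spatially uniform
        assert state.oxygen[0, 0] == pytest.approx(sol.y[0, -1], rel=1e-3)

    def test_refuses_unstable_time_step(self, params):
        unstable = params.replace(dt_oxygen=1.0)  # factor 0.4 > 0.25
        state = make_state(9, [[4, 4]])
        with pytest.raises(StabilityError):
            step_oxygen(state, build_consumption(state, unstable), unstable)


class TestQuasiSteady:
    def test_direct_matches_long_explicit_integration(self, params):
        """Dual-route check: the Newton steady state agrees with the
        fixed-step explicit integration to well under 0.1%."""
        state_d = make_state(21, [[10, 10]], fill="healthy")
        m = build_consumption(state_d, params)
        relax_to_quasi_steady(state_d, m, params, method="direct")
        state_e = make_state(21, [[10, 10]], fill="healthy")
        relax_to_quasi_steady(state_e, m, params, method="explicit",
                              tol=1e-9, max_iterations=400_000)
        assert np.abs(state_d.oxygen - state_e.oxygen).max() < 1e-3
        assert np.abs(state_d.oxygen - state_e.oxygen).max() < 1e-5

    def test_no_vessels_with_consumers_decays_to_zero(self, params):
        state = make_state(11, [], fill="tumour", c0=0.8)
        m = build_consumption(state, params)
        relax_to_quasi_steady(state, m, params, method="direct")
        assert state.oxygen.max() < 1e-6

    def test_vessels_everywhere_pin_the_field_at_one(self, params):
        coords = [(i, j) for i in range(5) for j in range(5)]
        state = make_state(5, coords, c0=0.0)
        m = build_consumption(state, params)
        info = relax_to_quasi_steady(state, m, params)
        assert info.converged
        assert np.all(state.oxygen == 1.0)

    def test_bounded_in_unit_interval(self, params, rng):
        pattern = vr.generate_random(31, 6, rng)
        state = TissueState.from_pattern(pattern, fill="tumour", c0=0.3)
        m = build_consumption(state, params)
        relax_to_quasi_steady(state, m, params)
        assert state.oxygen.min() >= 0.0 and state.oxygen.max() <= 1.0
        for _ in range(50):
            step_oxygen(state, m, params)
            assert state.oxygen.min() >= 0.0 and state.oxygen.max() <= 1.0

    def test_symmetric_layout_gives_symmetric_field(self, params):
        state = make_state(21, [[10, 10]], fill="healthy")
        m = build_consumption(state, params)
        relax_to_quasi_steady(state, m, params)
        c = state.oxygen
        assert np.abs(c - c[::-1, :]).max() < 1e-8
        assert np.abs(c - c[:, ::-1]).max() < 1e-8
        assert np.abs(c - c.T).max() < 1e-8

    def test_adding_a_vessel_never_lowers_the_steady_field(self, params):
        base = make_state(21, [[5, 5]], fill="healthy")
        relax_to_quasi_steady(base, build_consumption(base, params), params)
        more = make_state(21, [[5, 5], [15, 15]], fill="healthy")
        relax_to_quasi_steady(more, build_consumption(more, params), params)
        assert np.all(more.oxygen >= base.oxygen - 1e-8)

    def test_saturated_uptake_limit_matches_independent_linear_solve(self):
        """With K_m pushed to 1e-6 the uptake is constant wherever c is
        appreciable, so the steady field must match a dense direct solve
        of the linear constant-consumption problem assembled
        independently here."""
        params = vr.default_parameters(K_m_dim=5.14e-13 * 1e-6)
        N = 11
        coords = [[2, 2], [2, 8], [8, 2], [8, 8], [5, 5]]
        state = make_state(N, coords, fill="healthy")
        m = build_consumption(state, params)
        relax_to_quasi_steady(state, m, params, tol=1e-10)
        assert state.oxygen.min() > 1e-3  # constant-uptake regime holds

        # independent assembly: D * lap(c) = m * r_c, reflection edges
        vessel = state.vessel_mask
        unknowns = [(i, j) for i in range(N) for j in range(N)
                    if not vessel[i, j]]
        index = {site: k for k, site in enumerate(unknowns)}
        A = np.zeros((len(unknowns), len(unknowns)))
        rhs = np.zeros(len(unknowns))
        for (i, j), k in index.items():
            A[k, k] = -4.0
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if ii < 0 or ii >= N:
                    ii = i - di  # ghost reflection
                if jj < 0 or jj >= N:
                    jj = j - dj
                if vessel[ii, jj]:
                    rhs[k] -= params.D_c
                else:
                    A[k, index[(ii, jj)]] += 1.0
            rhs[k] += m[i, j] * params.r_c
        sol = np.linalg.solve(params.D_c * A, rhs)
        expected = np.ones((N, N))
        for (i, j), k in index.items():
            expected[i, j] = sol[k]
        assert np.abs(state.oxygen - expected).max() < 1e-3


class TestConsumptionField:
    def test_multipliers_by_type_and_flags(self, params):
        state = make_state(5, [[0, 0]], fill="empty")
        state.cell_grid[1, 1] = vr.HEALTHY
        state.cell_grid[2, 2] = vr.TUMOUR
        state.cell_grid[3, 3] = vr.TUMOUR
        state.proliferating[3, 3] = True
        m = build_consumption(state, params)
        assert m[0, 0] == 0.0          # vessel
        assert m[4, 4] == 0.0          # empty
        assert m[1, 1] == params.mu_H
        assert m[2, 2] == params.mu_H * params.mu_T_ratio
        assert m[3, 3] == params.mu_H * params.mu_T_ratio * params.r_p_factor

    def test_neighbour_sum_reflects_at_edges(self):
        c = np.arange(9.0).reshape(3, 3)
        s = _neighbour_sum(c)
        # corner (0,0): reflected neighbours are c[1,0] twice-mirrored
        assert s[0, 0] == c[1, 0] + c[1, 0] + c[0, 1] + c[0, 1]
        assert s[1, 1] == c[0, 1] + c[2, 1] + c[1, 0] + c[1, 2]
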