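"""Cross-bridge kinetics and the stretch-sensing evolution laws:
hand-computed rate values, tau-offset fixed points, conservation and
positivity invariants, steady states, and integrator convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from bayliss.chemistry import (
    FiberChemState,
    calcium,
    calcium_target,
    chem_steady_state,
    hai_murphy_matrix,
    hai_murphy_rhs,
    k25_rate,
    k25_target,
    lam_c_rate,
    lam_p_rate,
    mlck_rate,
    steady_fractions,
    step_chemistry,
)
from bayliss.errors import ParameterError
from bayliss.params import ChemParams


class TestRateFunctions:
    def test_mlck_zero_half_saturation(self, chem):
        assert mlck_rate(0.0, chem) == 0.0
        assert mlck_rate(chem.ca50, chem) == pytest.approx(0.5 * chem.eta)
        assert mlck_rate(1e9, chem) == pytest.approx(chem.eta, rel=1e-6)

    def test_calcium_macaulay(self, chem):
        assert calcium(1.0, 1.0, chem) == 0.0
        assert calcium(0.9, 1.0, chem) == 0.0
        assert calcium(1.2, 1.0, chem) == pytest.approx(0.5131 * 0.04)

    def test_calcium_target_values(self, chem):
        assert calcium_target(chem.lambda50_c, chem) == pytest.approx(0.5 * chem.gamma3)
        assert calcium_target(1e6, chem) == pytest.approx(chem.gamma3, rel=1e-9)
        assert calcium_target(1.0, chem) == pytest.approx(0.9 / 2.44)

    def test_k25_target_values(self, chem):
        assert k25_target(chem.lambda50_p, chem) == pytest.approx(0.5 * chem.gamma6)
        assert k25_target(1e9, chem) == pytest.approx(0.0, abs=1e-6)
        assert k25_target(1.2, chem) == pytest.approx(1.5 * (1.0 - 1.2 / 2.2))
        # strictly decreasing in lam
        lams = np.linspace(0.8, 1.6, 20)
        vals = [k25_target(l, chem) for l in lams]
        assert np.all(np.diff(vals) < 0.0)

    def test_zero_rate_fixed_points(self, chem):
        """The tau constructions make every evolution rate vanish exactly
        when its driving difference is zero (barriers inactive)."""
        assert lam_c_rate(0.0, chem) == pytest.approx(0.0, abs=1e-15)
        assert k25_rate(0.0, 1e3, chem) == pytest.approx(0.0, abs=1e-6 * abs(chem.k25_rate_max))
        # barrier inactive at large delta_lam_p
        assert lam_p_rate(0.0, 1.0, chem) == pytest.approx(0.0, abs=1e-15)

    def test_sigmoid_asymptotes(self, chem):
        assert lam_c_rate(-1e3, chem) == pytest.approx(chem.lamc_rate_max)
        assert lam_c_rate(1e3, chem) == pytest.approx(chem.lamc_rate_min)
        assert lam_p_rate(1e3, 1.0, chem) == pytest.approx(chem.lamp_rate_min)
        # maximal MLCP inhibition: k25 large -> constraint ~ 1
        assert k25_rate(1e3, 10.0, chem) == pytest.approx(chem.k25_rate_min)

    def test_k25_zero_suppresses_negative_branch(self, chem):
        # at k25 = 0 the (1 - e^{-zeta1 k25}) factor kills the negative term
        assert k25_rate(1e3, 0.0, chem) == pytest.approx(0.0, abs=1e-12)
        assert k25_rate(-1e3, 0.0, chem) == pytest.approx(chem.k25_rate_max - chem.k25_rate_min)

    def test_lam_p_barrier_at_wall(self, chem):
        # at delta_lam_p = delta_lamp_min the barrier has full strength
        val = lam_p_rate(0.0, chem.delta_lamp_min, chem)
        assert val == pytest.approx(-chem.lamp_rate_max, abs=1e-15)


class TestHaiMurphy:
    def test_pure_state_A_absorbing_without_mlck(self, chem):
        state = FiberChemState(1.0, 0.0, 0.0, 0.0, k25=1.0, lam_c_bar=1.0, lam_p_bar=1.0)
        rhs = hai_murphy_rhs(state, 0.0, chem)
        assert np.allclose(rhs, 0.0)

    def test_first_column_hand_value(self, chem):
        state = FiberChemState(1.0, 0.0, 0.0, 0.0, k25=1.82758, lam_c_bar=1.0, lam_p_bar=1.0)
        rhs = hai_murphy_rhs(state, 0.0812, chem)
        assert rhs[0] == pytest.approx(-0.0812)
        assert rhs[1] == pytest.approx(0.0812)
        assert rhs[2] == pytest.approx(0.0)
        assert rhs[3] == pytest.approx(0.0)

    def test_columns_sum_to_zero(self, chem, rng):
        A = hai_murphy_matrix(0.08, 1.2, chem)
        assert np.allclose(A.sum(axis=0), 0.0)
        n = rng.dirichlet(np.ones(4))
        state = FiberChemState(*n, k25=0.5, lam_c_bar=1.0, lam_p_bar=1.0)
        assert hai_murphy_rhs(state, 0.05, chem).sum() == pytest.approx(0.0, abs=1e-16)

    def test_negative_rate_rejected(self, chem):
        with pytest.raises(ParameterError):
            hai_murphy_matrix(-0.1, 1.0, chem)


class TestSteadyState:
    def test_null_space_residual(self, chem):
        n = steady_fractions(0.08, 0.7, chem)
        A = hai_murphy_matrix(0.08, 0.7, chem)
        assert np.linalg.norm(A @ n) < 1e-12
        assert n.sum() == pytest.approx(1.0)

    def test_zero_mlck_gives_pure_A(self, chem):
        n = steady_fractions(0.0, 0.7, chem)
        assert np.allclose(n, [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_backward_euler_preserves_fixed_point(self, chem):
        """The coupled fixed point persists under implicit stepping: a
        backward-Euler fixed point is a fixed point of the ODEs."""
        ss = chem_steady_state(1.05, chem)
        st = ss
        for _ in range(50):
            st = step_chemistry(st, 1.05, 10.0, chem)
        assert np.max(np.abs(st.fractions - ss.fractions)) < 1e-9
        assert st.k25 == pytest.approx(ss.k25, abs=1e-9)
        assert st.lam_p_bar == pytest.approx(ss.lam_p_bar, abs=1e-9)
        assert st.lam_c_bar == pytest.approx(ss.lam_c_bar, abs=1e-9)

    def test_frozen_rate_fractions_converge_to_null_space(self, chem):
        """With the reaction rates held fixed, long-time integration of the
        fraction ODEs lands on the rate-matrix null space (< 1e-6)."""
        from dataclasses import replace

        p = replace(chem, ca_const=0.35)
        k16 = mlck_rate(0.35, p)
        target = steady_fractions(k16, p.k25_start, p)
        st = FiberChemState.initial(p)
        for _ in range(6000):  # 3e5 s
            st = step_chemistry(st, 1.0, 50.0, p, k25_frozen=True)
        assert np.max(np.abs(st.fractions - target)) < 1e-6

    def test_steady_nc_monotone_in_stretch(self, chem):
        """More stretch -> more MLCK, less MLCP -> more cycling heads."""
        ncs = [chem_steady_state(l, chem).nC for l in np.linspace(1.0, 1.4, 6)]
        assert np.all(np.diff(ncs) >= -1e-12)


class TestStepChemistry:
    def test_conservation_long_run(self, chem):
        st = FiberChemState.initial(chem)
        for _ in range(10_000):
            st = step_chemistry(st, 1.1, 0.5, chem)
            s = st.nA + st.nB + st.nC + st.nD
            assert abs(s - 1.0) < 1e-10

    def test_small_dt_consistency(self, chem):
        """dt -> 0: the state change is O(dt)."""
        st = chem_steady_state(1.1, chem)
        st.nA, st.nD = st.nA + 0.1, st.nD - 0.1  # push off equilibrium
        deltas = []
        for dt in (1e-2, 1e-3, 1e-4):
            new = step_chemistry(st, 1.1, dt, chem)
            deltas.append(np.max(np.abs(new.fractions - st.fractions)))
        assert deltas[0] < 0.05
        assert deltas[1] == pytest.approx(deltas[0] / 10.0, rel=0.2)
        assert deltas[2] == pytest.approx(deltas[1] / 10.0, rel=0.2)

    def test_first_order_convergence(self, chem):
        """Backward Euler converges at first order to an explicit
        high-accuracy reference of the full coupled system."""

        lam = 1.12
        T = 10.0

        def rhs(t, y):
            nA, nB, nC, nD, k25, lamc, lamp = y
            ca = calcium(lam, lamc, chem)
            k16 = mlck_rate(ca, chem)
            A = hai_murphy_matrix(k16, max(k25, 0.0), chem)
            dn = A @ np.array([nA, nB, nC, nD])
            dlamc = lam_c_rate(calcium_target(lam, chem) - ca, chem)
            dk = k25_rate(lam - lamp, max(k25, 0.0), chem)
            dlamp = lam_p_rate(k25_target(lam, chem) - k25, lam - lamp, chem)
            return [*dn, dk, dlamc, dlamp]

        y0 = [1.0, 0.0, 0.0, 0.0, chem.k25_start, chem.lamc_start, chem.lamp_start]
        ref = solve_ivp(rhs, (0.0, T), y0, rtol=1e-11, atol=1e-13, method="RK45").y[:, -1]

        errs = []
        for dt in (0.5, 0.25, 0.125):
            st = FiberChemState.initial(chem)
            for _ in range(int(round(T / dt))):
                st = step_chemistry(st, lam, dt, chem)
            approx = np.array([st.nA, st.nB, st.nC, st.nD, st.k25, st.lam_c_bar, st.lam_p_bar])
            errs.append(np.max(np.abs(approx - ref)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all((orders > 0.8) & (orders < 1.2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_positivity_random_histories(self, chem, seed):
        """Fractions stay in [0,1] and k25 stays non-negative over
        randomized bounded stretch histories."""
        gen = np.random.default_rng(seed)
        state = FiberChemState.initial(chem)
        lam = 1.0
        for _ in range(300):
            lam = float(np.clip(lam + 0.02 * gen.standard_normal(), 0.8, 1.5))
            state = step_chemistry(state, lam, 1.0, chem)
            n = state.fractions
            assert np.all(n >= -1e-12) and np.all(n <= 1.0 + 1e-12)
            assert state.k25 >= 0.0
            assert abs(n.sum() - 1.0) < 1e-10


def test_degenerate_sigmoid_constant_rate():
    """Equal rate bounds short-circuit the tau construction."""
    p = ChemParams(lamc_rate_min=0.0, lamc_rate_max=0.0)
    assert p.tau_c == 0.0
    assert lam_c_rate(123.0, p) == 0.0
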