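"""Core model: Hill kinetics, right-hand sides, quasi-steady state, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import yaptaz as yz
from yaptaz.model import reduced_rhs_components, state_bounds


class TestHill:
    @pytest.mark.parametrize("J,n", [(0.1, 1.0), (0.5, 2.0), (1.461, 4.0)])
    def test_half_saturation_and_limits(self, J, n):
        assert yz.hill_activation(J, J, n) == pytest.approx(0.5)
        assert yz.hill_activation(0.0, J, n) == 0.0
        assert yz.hill_activation(2 * 0.5, 0.5, 2) == pytest.approx(0.8)

    @given(x=st.floats(0, 50), J=st.floats(0.01, 10), n=st.floats(1, 6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_activator_repressor_complementarity(self, x, J, n):
        act = yz.hill_activation(x, J, n)
        rep = J**n / (x**n + J**n)
        assert act + rep == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= act <= 1.0

    def test_strictly_increasing(self):
        xs = np.linspace(0, 5, 200)
        vals = yz.hill_activation(xs, 0.7, 4)
        assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            yz.hill_activation(1.0, -0.5, 2)
        with pytest.raises(ValueError):
            yz.hill_activation(-1.0, 0.5, 2)


class TestRhs:
    def test_all_species_zero_leaves_only_basal_terms(self, std):
        d = yz.full_rhs(np.zeros(5), std)
        assert d[0] == pytest.approx(std.kL1)
        assert d[1] == pytest.approx(std.kYTup0)
        assert d[2] == 0.0
        assert d[3] == pytest.approx(std.kS1)
        assert d[4] == pytest.approx(std.kN1)

    def test_degradation_term_is_linear_in_kL3(self, std, rng):
        state = rng.uniform(0.05, 2.0, 5)
        doubled = std.replace(kL3=2 * std.kL3)
        base = yz.full_rhs(state, std)
        pert = yz.full_rhs(state, doubled)
        assert pert[0] - base[0] == pytest.approx(-std.kL3 * state[0])

    def test_homeostatic_equilibrium_zeroes_full_rhs(self, std):
        eq = yz.find_steady_states(std)[0]
        h = yz.homeostatic_state(std)
        assert np.linalg.norm(yz.full_rhs(np.asarray(h), std)) < 1e-8
        assert h.YT_up == pytest.approx(eq.state.YT_up, abs=1e-8)

    def test_reduced_dL_matches_full_dL(self, std, rng):
        for _ in range(5):
            L, Y = rng.uniform(0.01, 2.0, 2)
            full = yz.full_rhs([L, Y, 0.3, 0.5, 0.5], std)
            red = yz.reduced_rhs([L, Y], std)
            assert red[0] == pytest.approx(full[0])

    def test_negative_state_rejected(self, std):
        with pytest.raises(ValueError):
            yz.full_rhs([-0.1, 0, 0, 0, 0], std)
        with pytest.raises(ValueError):
            yz.reduced_rhs([0.1, -0.2], std)


class TestQss:
    def test_zero_ytup_gives_basal_ratios(self, std):
        q = yz.qss_values(0.0, 0.5, std)
        assert q.S_star == pytest.approx(std.kS1 / std.kS3)
        assert q.N_star == pytest.approx(std.kN1 / std.kN3)
        # no phosphorylation influx at YT_up = 0 -> YT_p* = 0
        assert q.YTp_star == pytest.approx(0.0, abs=1e-12)

    def test_qss_zeroes_fast_subsystem(self, std, rng):
        for _ in range(10):
            Y, L = rng.uniform(0.0, 3.0, 2)
            q = yz.qss_values(Y, L, std)
            d = yz.full_rhs([L, Y, q.YTp_star, q.S_star, q.N_star], std)
            assert abs(d[2]) < 1e-10  # dYT_p/dt
            assert abs(d[3]) < 1e-12  # dS/dt
            assert abs(d[4]) < 1e-12  # dN/dt

    def test_qss_bounds(self, std, rng):
        for _ in range(20):
            Y, L = rng.uniform(0.0, 5.0, 2)
            q = yz.qss_values(Y, L, std)
            assert std.kS1 / std.kS3 <= q.S_star <= (std.kS1 + std.kS2) / std.kS3
            assert std.kN1 / std.kN3 <= q.N_star <= (std.kN1 + std.kN2) / std.kN3
            assert q.YTp_star >= 0

    def test_closed_form_matches_bisection_root(self, std, rng):
        from yaptaz.model import _phospho_rate

        for _ in range(10):
            Y, L = rng.uniform(0.01, 3.0, 2)
            q = yz.qss_values(Y, L, std)
            phos = _phospho_rate(Y, L, std)

            def resid(yp):
                return phos - std.kYTup4 * yp / (yp + std.JYTup4) - std.kYTp1 * yp

            ref = brentq(resid, 0.0, phos / std.kYTp1 + 1.0, xtol=1e-14)
            assert q.YTp_star == pytest.approx(ref, abs=1e-10)


class TestIntegration:
    def test_start_at_equilibrium_stays(self, std):
        h = np.asarray(yz.homeostatic_state(std))
        traj = yz.integrate(h, std, t_end=100.0)
        assert np.allclose(traj.terminal, h, atol=1e-6)

    def test_all_initial_conditions_converge_to_homeostasis(self, std, rng):
        """Monostable standard regime: every trajectory reaches the same state."""
        target = yz.find_steady_states(std)[0].state.YT_up
        for _ in range(6):
            y0 = rng.uniform(0.0, 2.0, 2)
            traj = yz.integrate(y0, std, t_end=720.0, which="reduced")
            assert traj.terminal[1] == pytest.approx(target, abs=1e-4)
            assert np.linalg.norm(yz.reduced_rhs(traj.terminal, std)) < 1e-6

    def test_full_and_reduced_agree_at_terminal(self, std, rng):
        L0, Y0 = rng.uniform(0.05, 1.5, 2)
        q = yz.qss_values(Y0, L0, std)
        full = yz.integrate([L0, Y0, q.YTp_star, q.S_star, q.N_star], std, 720.0)
        red = yz.integrate([L0, Y0], std, 720.0, which="reduced")
        assert full.terminal[0] == pytest.approx(red.terminal[0], abs=1e-3)
        assert full.terminal[1] == pytest.approx(red.terminal[1], abs=1e-3)

    def test_nonnegativity_and_boundedness(self, std, rng):
        B_L, B_YT = state_bounds(std)
        for _ in range(4):
            y0 = rng.uniform(0.0, 1.0, 5)
            traj = yz.integrate(y0, std, t_end=200.0)
            assert np.all(traj.states >= 0)
            assert np.all(traj.states[:, 0] <= B_L)
            assert np.all(traj.states[:, 1] <= B_YT)

    def test_rejects_bad_inputs(self, std):
        with pytest.raises(ValueError):
            yz.integrate([0.1, 0.1], std, t_end=-1.0, which="reduced")
        with pytest.raises(ValueError):
            yz.integrate([-0.1, 0.1], std, t_end=1.0, which="reduced")


class TestParameterSet:
    def test_positivity_enforced(self, std):
        with pytest.raises(ValueError):
            std.replace(kL1=-0.1)
        with pytest.raises(ValueError):
            std.replace(n=0.5)

    def test_swept_parameter_may_be_negative(self, std):
        p = std.replace(kYTup0=-0.002)
        dL, dY = reduced_rhs_components(0.1, 0.1, p)
        assert np.isfinite(dL) and np.isfinite(dY)

    def test_roundtrip_dict(self, std):
        assert yz.ParameterSet.from_dict(std.to_dict()) == std
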