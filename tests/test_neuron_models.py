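"""Unit tests for the single-neuron currents and gating kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from tcloop import neuron_models as nm
from tcloop.params import default_params


@pytest.fixture(scope="module")
def tc_block():
    return default_params()["neurons"]["rodent"]["TC"]


class TestHHCurrent:
    def test_zero_driving_force(self):
        p = nm.MembraneParams()
        gate = nm.HHGatingState(m=0.5, h=0.5, n=0.5)
        I_Na, _, _ = nm.hh_current(p.E_Na, gate, p)
        assert I_Na == 0.0

    def test_closed_gates_pass_no_current(self):
        p = nm.MembraneParams()
        I_Na, I_K, _ = nm.hh_current(-30.0, nm.HHGatingState(m=0.0, h=1.0, n=0.0), p)
        assert I_Na == 0.0 and I_K == 0.0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            nm.hh_current(float("nan"), nm.HHGatingState(), nm.MembraneParams())

    def test_resting_potential_matches_bisection_oracle(self):
        """The HH-only rest must agree with an independent root-finder."""
        p = nm.MembraneParams()

        def steady_current(V):
            gate = nm.hh_steady_state(V, p.V_T)
            return sum(nm.hh_current(V, gate, p))

        v_oracle = brentq(steady_current, -90.0, -60.0, xtol=1e-9)
        rest = nm.resting_state("Ctx", p)
        assert rest.V == pytest.approx(v_oracle, abs=1e-6)

    def test_rate_functions_continuous_at_singularities(self):
        # alpha_m has a removable singularity where 13 - (V - V_T) = 0
        V_sing = -55.0 + 13.0
        rates = np.array(nm.hh_rates(np.array([V_sing - 1e-7, V_sing, V_sing + 1e-7])))
        assert np.all(np.isfinite(rates))
        assert np.allclose(rates[:, 0], rates[:, 1], rtol=1e-4)


class TestTCurrent:
    def test_zero_cases(self):
        p = nm.TCurrentParams(g_Ca=2.0, E_Ca=120.0, activation_exponent=2)
        assert nm.t_current(120.0, 0.5, 0.5, p) == 0.0
        assert nm.t_current(-60.0, 0.5, 0.0, p) == 0.0

    def test_exponent_ratio_trn_vs_tc(self):
        """At identical (V, m, h, g_Ca), I_TRN / I_TC = 1/m (exponents 2 vs 3)."""
        trn = nm.TCurrentParams(g_Ca=2.0, activation_exponent=2)
        tc = nm.TCurrentParams(g_Ca=2.0, activation_exponent=3)
        for m in (0.2, 0.5, 0.9):
            ratio = nm.t_current(-60.0, m, 0.5, trn) / nm.t_current(-60.0, m, 0.5, tc)
            assert ratio == pytest.approx(1.0 / m, rel=1e-12)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            nm.TCurrentParams(activation_exponent=4)

    @pytest.mark.parametrize("kind,expo", [("TRN", 2), ("TC", 3)])
    def test_gating_relaxes_to_steady_state(self, kind, expo):
        """Clamped-V integration must land on m_inf/h_inf to 1e-8."""
        p = nm.TCurrentParams(activation_exponent=expo)
        V = -65.0
        kin = nm.trn_t_kinetics if expo == 2 else nm.tc_t_kinetics
        m_inf, _, h_inf, _ = kin(V)

        def rhs(t, y):
            return nm.t_gate_derivatives(V, y[0], y[1], p)

        sol = solve_ivp(rhs, [0.0, 5000.0], [0.0, 0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(float(m_inf), abs=1e-8)
        assert sol.y[1, -1] == pytest.approx(float(h_inf), abs=1e-8)


class TestHCurrent:
    def test_zero_cases(self):
        s = nm.HCurrentState(S1=0.3, F1=0.3, S2=0.1, F2=0.1)
        assert nm.h_current(s.params.E_H, s) == 0.0
        s0 = nm.HCurrentState(S1=0.0, S2=0.0, F1=0.5, F2=0.1)
        assert nm.h_current(-60.0, s0) == 0.0

    def test_fixed_point_matches_nullspace_oracle(self):
        """Long clamped-V integration must match the linear-system solution."""
        p = nm.HCurrentParams()
        V = -75.0
        h_inf, tau_S, tau_F = nm.h_gate_kinetics(V)
        h_inf, tau_S, tau_F = float(h_inf), float(tau_S), float(tau_F)

        # oracle: solve the linear steady-state system A x = b directly;
        # the scheme decouples into S- and F-subsystems with x = (X1, X2)
        aS, bS = h_inf / tau_S, (1 - h_inf) / tau_S
        aF, bF = h_inf / tau_F, (1 - h_inf) / tau_F
        A_S = np.array([[-(aS + bS + p.C), -aS + p.k2], [p.C, -p.k2]])
        b_S = np.array([-aS, 0.0])
        S1, S2 = np.linalg.solve(A_S, b_S)
        A_F = np.array([[-(aF + bF + p.C), -aF + p.k2], [p.C, -p.k2]])
        b_F = np.array([-aF, 0.0])
        F1, F2 = np.linalg.solve(A_F, b_F)

        def rhs(t, y):
            s = nm.HCurrentState(S1=y[0], F1=y[1], S2=y[2], F2=y[3], params=p)
            return nm.h_state_derivatives(V, s)

        sol = solve_ivp(rhs, [0.0, 2e5], [0.0, 0.0, 0.0, 0.0],
                        rtol=1e-11, atol=1e-13, method="LSODA")
        assert sol.y[0, -1] == pytest.approx(S1, abs=1e-8)
        assert sol.y[2, -1] == pytest.approx(S2, abs=1e-8)
        assert sol.y[1, -1] == pytest.approx(F1, abs=1e-8)
        assert sol.y[3, -1] == pytest.approx(F2, abs=1e-8)

        closed = nm._h_fixed_point(V, p)
        assert closed.S1 == pytest.approx(S1, abs=1e-10)
        assert closed.F2 == pytest.approx(F2, abs=1e-10)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            nm.HCurrentState(S1=0.8, S2=0.4)


class TestMembraneDerivative:
    def test_all_conductances_zero_gives_zero(self):
        p = nm.MembraneParams(g_leak=0.0, g_Na=0.0, g_K=0.0)
        st = nm.NeuronState(V=-65.0, hh=nm.HHGatingState(0.3, 0.5, 0.2),
                            neuron_kind="Ctx")
        assert nm.membrane_derivative(st, 0.0, 0.0, p) == 0.0

    def test_ctx_has_no_intrinsic_current(self):
        st = nm.NeuronState(V=-60.0, hh=nm.HHGatingState(), neuron_kind="Ctx")
        assert nm.intrinsic_current(st) == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            nm.NeuronState(V=-60.0, hh=nm.HHGatingState(), neuron_kind="Purkinje")

    def test_derivative_matches_reference_integrator_first_step(self, tc_block):
        """dV/dt must equal the finite difference of a high-accuracy solver."""
        p = nm.membrane_params_from_config(tc_block)
        tp = nm.TCurrentParams(g_Ca=tc_block["g_Ca"], E_Ca=tc_block["E_Ca"],
                               activation_exponent=3)
        hp = nm.HCurrentParams(g_H=tc_block["g_H"], E_H=tc_block["E_H"],
                               k2=tc_block["k2"], C=tc_block["C"])
        st = nm.resting_state("TC", p, tp, hp)
        st.V += 5.0  # perturb off the fixed point
        I_ext = 0.7

        def rhs(t, y):
            hh = nm.HHGatingState(*np.clip(y[1:4], 0, 1))
            hs = nm.HCurrentState(S1=y[6], F1=y[7], S2=y[8], F2=y[9], params=hp)
            state = nm.NeuronState(V=y[0], hh=hh, neuron_kind="TC",
                                   t_gate=(y[4], y[5]), h_state=hs)
            am, bm, ah, bh, an, bn = nm.hh_rates(y[0], p.V_T)
            dm = am * (1 - y[1]) - bm * y[1]
            dh = ah * (1 - y[2]) - bh * y[2]
            dn = an * (1 - y[3]) - bn * y[3]
            dmT, dhT = nm.t_gate_derivatives(y[0], y[4], y[5], tp)
            dS1, dF1, dS2, dF2 = nm.h_state_derivatives(y[0], hs)
            dV = nm.membrane_derivative(state, 0.0, I_ext, p, tp)
            return [dV, dm, dh, dn, dmT, dhT, dS1, dF1, dS2, dF2]

        y0 = [st.V, st.hh.m, st.hh.h, st.hh.n, *st.t_gate,
              st.h_state.S1, st.h_state.F1, st.h_state.S2, st.h_state.F2]
        dt = 1e-4
        sol = solve_ivp(rhs, [0.0, dt], y0, rtol=1e-12, atol=1e-12)
        fd = (sol.y[0, -1] - y0[0]) / dt
        analytic = rhs(0.0, y0)[0]
        assert fd == pytest.approx(analytic, abs=1e-4)


class TestGatingBounds:
    def test_gates_stay_in_unit_interval_on_random_voltage_paths(self):
        """Euler steps at dt = 0.025 ms must keep every gate inside [0, 1]."""
        rng = np.random.default_rng(7)
        dt = 0.025
        for _ in range(20):
            V = -70.0
            m = h = n = mT = hT = 0.5
            for _ in range(2000):
                V = np.clip(V + rng.normal(0, 2.0), -110.0, 50.0)
                am, bm, ah, bh, an, bn = nm.hh_rates(V)
                m += dt * (am * (1 - m) - bm * m)
                h += dt * (ah * (1 - h) - bh * h)
                n += dt * (an * (1 - n) - bn * n)
                dmT, dhT = nm.t_gate_derivatives(
                    V, mT, hT, nm.TCurrentParams(activation_exponent=3))
                mT += dt * dmT
                hT += dt * dhT
                for g in (m, h, n, mT, hT):
                    assert -1e-9 <= g <= 1.0 + 1e-9
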