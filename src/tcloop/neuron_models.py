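"""Single-compartment conductance-based neuron models.

Four cell kinds make up the thalamocortical loop: cortical (Ctx), thalamic
relay (TC), thalamic reticular (TRN) and, in the primate, local thalamic
interneurons (IN).  Every cell carries Hodgkin-Huxley Na+/K+/leak currents;
TRN and TC cells add a low-threshold Ca2+ current I_T (activation exponent 2
for TRN, 3 for TC) responsible for burst and rebound-burst firing, and TC
cells further add the hyperpolarization-activated cation current I_H with
slow/fast open states (S1, F1) and locked states (S2, F2).

The membrane equation, with every current written outward-positive, is

    Cm dV/dt = -I_L - I_Na - I_K - I_intrinsic - I_syn + I_ext

Units: mV, ms, uF/cm^2, mS/cm^2, uA/cm^2.

Rate functions are the canonical published kinetics for each current
(Traub-style HH rates with a threshold-shift parameter V_T;
Huguenard-Prince-style TRN I_T; Destexhe-style TC I_T and the two-state
slow/fast I_H), pre-adjusted to physiological temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

NEURON_KINDS = ("Ctx", "TC", "TRN", "IN")


# ---------------------------------------------------------------------------
# parameter / state containers
# ---------------------------------------------------------------------------

@dataclass
class MembraneParams:
    """Passive + HH constants for one cell (mS/cm^2, mV, uF/cm^2)."""

    Cm: float = 1.0
    g_leak: float = 0.1
    E_leak: float = -70.0
    g_Na: float = 50.0
    E_Na: float = 50.0
    g_K: float = 5.0
    E_K: float = -90.0
    V_T: float = -55.0  # threshold shift applied inside the HH rate functions

    def __post_init__(self):
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        for name in ("g_leak", "g_Na", "g_K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.E_Na > self.E_K:
            raise ValueError("E_Na must exceed E_K")


@dataclass
class HHGatingState:
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0

    def __post_init__(self):
        for name in ("m", "h", "n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gating variable {name}={v} outside [0, 1]")


@dataclass
class TCurrentParams:
    """Low-threshold Ca2+ current; exponent 2 -> TRN kinetics, 3 -> TC."""

    g_Ca: float = 2.0
    E_Ca: float = 120.0
    activation_exponent: int = 2

    def __post_init__(self):
        if self.activation_exponent not in (2, 3):
            raise ValueError("activation_exponent must be 2 (TRN) or 3 (TC)")
        if self.g_Ca < 0:
            raise ValueError("g_Ca must be non-negative")


@dataclass
class HCurrentParams:
    g_H: float = 0.017
    E_H: float = -43.0
    k2: float = 4e-4   # locked -> open rate (1/ms)
    C: float = 2e-4    # open -> locked rate (1/ms)
    strict_printed_form: bool = False  # couple dF1/dt to -C*S1 instead of -C*F1


@dataclass
class HCurrentState:
    """Slow (S) and fast (F) gates, each with open (1) and locked (2) states."""

    S1: float = 0.0
    F1: float = 0.0
    S2: float = 0.0
    F2: float = 0.0
    params: HCurrentParams = field(default_factory=HCurrentParams)

    def __post_init__(self):
        for name in ("S1", "F1", "S2", "F2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.S1 + self.S2 > 1.0 + 1e-9 or self.F1 + self.F2 > 1.0 + 1e-9:
            raise ValueError("open + locked fractions exceed 1")


@dataclass
class NeuronState:
    V: float
    hh: HHGatingState
    neuron_kind: str = "Ctx"
    t_gate: tuple[float, float] | None = None       # (m, h) for I_T
    h_state: HCurrentState | None = None            # TC only

    def __post_init__(self):
        if self.neuron_kind not in NEURON_KINDS:
            raise ValueError(f"unknown neuron kind {self.neuron_kind!r}")
        if self.neuron_kind in ("TC", "TRN") and self.t_gate is None:
            raise ValueError(f"{self.neuron_kind} neuron requires t_gate")
        if self.neuron_kind == "TC" and self.h_state is None:
            raise ValueError("TC neuron requires h_state")


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def _vtrap(x, scale):
    """x / (exp(x/scale) - 1) with its removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / scale) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(small, scale * (1.0 - x / (2.0 * scale)),
                   safe / np.expm1(safe / scale))
    return out if out.ndim else float(out)


def hh_rates(V, V_T=-55.0):
    """Traub-style HH rate constants (1/ms) at the shifted voltage V - V_T."""
    v = np.asarray(V, dtype=float) - V_T
    alpha_m = 0.32 * _vtrap(13.0 - v, 4.0)
    beta_m = 0.28 * _vtrap(v - 40.0, 5.0)
    alpha_h = 0.128 * np.exp((17.0 - v) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp((40.0 - v) / 5.0))
    alpha_n = 0.032 * _vtrap(15.0 - v, 5.0)
    beta_n = 0.5 * np.exp((10.0 - v) / 40.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def hh_steady_state(V, V_T=-55.0) -> HHGatingState:
    am, bm, ah, bh, an, bn = hh_rates(V, V_T)
    return HHGatingState(m=float(am / (am + bm)), h=float(ah / (ah + bh)),
                         n=float(an / (an + bn)))


def trn_t_kinetics(V):
    """TRN I_T steady states and time constants (m_inf, tau_m, h_inf, tau_h)."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V + 52.0) / 7.4))
    h_inf = 1.0 / (1.0 + np.exp((V + 80.0) / 5.0))
    tau_m = 1.0 + 0.33 / (np.exp((V + 27.0) / 10.0) + np.exp(-(V + 102.0) / 15.0))
    tau_h = 28.3 + 0.33 / (np.exp((V + 48.0) / 4.0) + np.exp(-(V + 407.0) / 50.0))
    return m_inf, tau_m, h_inf, tau_h


def tc_t_kinetics(V):
    """TC I_T steady states and time constants, temperature-adjusted."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V + 57.0) / 6.2))
    h_inf = 1.0 / (1.0 + np.exp((V + 81.0) / 4.0))
    tau_m = (0.612 + 1.0 / (np.exp(-(V + 132.0) / 16.7) + np.exp((V + 16.8) / 18.2))) / 3.74
    tau_h = np.where(
        V < -80.0,
        np.exp((V + 467.0) / 66.6) / 3.73,
        (28.0 + np.exp(-(V + 22.0) / 10.5)) / 3.73,
    )
    return m_inf, tau_m, h_inf, tau_h


def h_gate_kinetics(V):
    """I_H open-state kinetics: (h_inf, tau_S, tau_F) in mV/ms."""
    V = np.asarray(V, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((V + 68.9) / 6.5))
    tau_S = np.exp((V + 183.6) / 15.24)
    tau_F = np.exp((V + 158.6) / 11.2) / (1.0 + np.exp((V + 75.0) / 5.5))
    return h_inf, tau_S, tau_F


# ---------------------------------------------------------------------------
# currents (outward-positive)
# ---------------------------------------------------------------------------

def hh_current(V, gate: HHGatingState, p: MembraneParams):
    """(I_Na, I_K, I_L) in uA/cm^2."""
    if not math.isfinite(V):
        raise ValueError("non-finite membrane potential")
    I_Na = p.g_Na * gate.m ** 3 * gate.h * (V - p.E_Na)
    I_K = p.g_K * gate.n ** 4 * (V - p.E_K)
    I_L = p.g_leak * (V - p.E_leak)
    return I_Na, I_K, I_L


def t_current(V, m, h, p: TCurrentParams):
    """Low-threshold Ca2+ current I_T = g_Ca * m^k * h * (V - E_Ca)."""
    if not (0.0 <= m <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("T-current gates must lie in [0, 1]")
    return p.g_Ca * m ** p.activation_exponent * h * (V - p.E_Ca)


def t_gate_derivatives(V, m, h, p: TCurrentParams):
    """(dm/dt, dh/dt): first-order relaxation to the kind-specific kinetics."""
    kin = trn_t_kinetics if p.activation_exponent == 2 else tc_t_kinetics
    m_inf, tau_m, h_inf, tau_h = kin(V)
    return (m_inf - m) / tau_m, (h_inf - h) / tau_h


def h_current(V, s: HCurrentState):
    """I_H = g_H * (S1+S2) * (F1+F2) * (V - E_H)."""
    p = s.params
    return p.g_H * (s.S1 + s.S2) * (s.F1 + s.F2) * (V - p.E_H)


def h_state_derivatives(V, s: HCurrentState):
    """(dS1, dF1, dS2, dF2)/dt for the four-state I_H scheme.

    Open states relax voltage-dependently and exchange with voltage-independent
    locked states (k2: locked->open, C: open->locked).  The locked-state
    closure dX2/dt = C*X1 - k2*X2 conserves each gate's total fraction <= 1.
    """
    p = s.params
    h_inf, tau_S, tau_F = h_gate_kinetics(V)
    alpha_S, beta_S = h_inf / tau_S, (1.0 - h_inf) / tau_S
    alpha_F, beta_F = h_inf / tau_F, (1.0 - h_inf) / tau_F
    dS1 = alpha_S * (1.0 - s.S1 - s.S2) - beta_S * s.S1 + p.k2 * s.S2 - p.C * s.S1
    lock_F = s.S1 if p.strict_printed_form else s.F1
    dF1 = alpha_F * (1.0 - s.F1 - s.F2) - beta_F * s.F1 + p.k2 * s.F2 - p.C * lock_F
    dS2 = p.C * s.S1 - p.k2 * s.S2
    dF2 = p.C * s.F1 - p.k2 * s.F2
    return dS1, dF1, dS2, dF2


def intrinsic_current(state: NeuronState, t_params: TCurrentParams | None = None):
    """Sum of the intrinsic currents appropriate to the cell kind."""
    kind = state.neuron_kind
    if kind in ("Ctx", "IN"):
        return 0.0
    if t_params is None:
        t_params = TCurrentParams(activation_exponent=2 if kind == "TRN" else 3)
    m, h = state.t_gate
    I = t_current(state.V, m, h, t_params)
    if kind == "TC":
        I += h_current(state.V, state.h_state)
    return I


def membrane_derivative(state: NeuronState, I_syn: float, I_ext: float,
                        p: MembraneParams,
                        t_params: TCurrentParams | None = None):
    """dV/dt (mV/ms) for the full membrane equation."""
    I_Na, I_K, I_L = hh_current(state.V, state.hh, p)
    I_int = intrinsic_current(state, t_params)
    return (-I_L - I_Na - I_K - I_int - I_syn + I_ext) / p.Cm


def resting_state(kind: str, p: MembraneParams,
                  t_params: TCurrentParams | None = None,
                  h_params: HCurrentParams | None = None,
                  v_bounds=(-90.0, -40.0)) -> NeuronState:
    """Quiescent fixed point: V* where total steady-state current vanishes.

    Solves I_total(V) = 0 by bisection with every gate at its steady state
    for the clamped voltage; used for initial conditions.
    """
    if kind not in NEURON_KINDS:
        raise ValueError(f"unknown neuron kind {kind!r}")
    if t_params is None and kind in ("TC", "TRN"):
        t_params = TCurrentParams(activation_exponent=2 if kind == "TRN" else 3)
    if h_params is None and kind == "TC":
        h_params = HCurrentParams()

    def total_current(V):
        gate = hh_steady_state(V, p.V_T)
        I_Na, I_K, I_L = hh_current(V, gate, p)
        I = I_Na + I_K + I_L
        if kind in ("TC", "TRN"):
            kin = trn_t_kinetics if kind == "TRN" else tc_t_kinetics
            m_inf, _, h_inf, _ = kin(V)
            I += t_current(V, float(m_inf), float(h_inf), t_params)
        if kind == "TC":
            I += h_current(V, _h_fixed_point(V, h_params))
        return I

    # the steady-state I-V curve can cross zero more than once (window
    # currents); take the lowest crossing, which is the hyperpolarized stable
    # fixed point, then refine by bisection
    grid = np.arange(v_bounds[0], v_bounds[1] + 0.25, 0.5)
    vals = np.array([total_current(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)
    if len(sign_change) == 0:
        raise ValueError("no resting potential bracketed in v_bounds")
    k = sign_change[0]
    lo, hi = float(grid[k]), float(grid[k + 1])
    flo = float(vals[k])
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = total_current(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    V = 0.5 * (lo + hi)

    hh = hh_steady_state(V, p.V_T)
    t_gate = None
    h_state = None
    if kind in ("TC", "TRN"):
        kin = trn_t_kinetics if kind == "TRN" else tc_t_kinetics
        m_inf, _, h_inf, _ = kin(V)
        t_gate = (float(m_inf), float(h_inf))
    if kind == "TC":
        h_state = _h_fixed_point(V, h_params)
    return NeuronState(V=V, hh=hh, neuron_kind=kind, t_gate=t_gate, h_state=h_state)


def _h_fixed_point(V, p: HCurrentParams) -> HCurrentState:
    """Steady state of the four-state I_H scheme at clamped V (closed form)."""
    h_inf, tau_S, tau_F = h_gate_kinetics(V)
    out = {}
    for tau, names in ((float(tau_S), ("S1", "S2")), (float(tau_F), ("F1", "F2"))):
        alpha, beta = float(h_inf) / tau, (1.0 - float(h_inf)) / tau
        # 0 = a(1 - x1 - x2) - b x1 + k2 x2 - C x1 ; 0 = C x1 - k2 x2
        # substituting x2 = (C/k2) x1 cancels the exchange terms:
        ratio = p.C / p.k2
        x1 = alpha / (alpha + beta + alpha * ratio)
        out[names[0]], out[names[1]] = x1, ratio * x1
    return HCurrentState(params=p, **out)


def membrane_params_from_config(block: dict) -> MembraneParams:
    keys = ("Cm", "g_leak", "E_leak", "g_Na", "E_Na", "g_K", "E_K", "V_T")
    return MembraneParams(**{k: block[k] for k in keys})
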