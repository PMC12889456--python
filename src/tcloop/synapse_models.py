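"""Kinetic synapse models.

Transmitter release is a sigmoid function of presynaptic voltage.  Ionotropic
receptors (AMPA, NMDA, GABA_A) follow first-order binding kinetics of the
open fraction m; metabotropic receptors (GABA_B, mGluR) add a second-messenger
cascade: activated receptor fraction r drives messenger concentration s, and
the channel opens with Hill saturation s^n / (s^n + Kd).  mGluR reuses the
GABA_B cascade with a 0 mV reversal, matching AMPA, so it is excitatory.

All currents are outward-positive: I = g * gate * (V_post - E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IONOTROPIC = ("AMPA", "NMDA", "GABA_A")
METABOTROPIC = ("GABA_B", "mGluR")
RECEPTORS = IONOTROPIC + METABOTROPIC


@dataclass
class TransmitterParams:
    """Sigmoid pulse of transmitter vs presynaptic voltage."""

    T_max: float = 1.0   # mM
    V_t: float = 2.0     # mV, half-activation
    K_p: float = 5.0     # mV, slope

    def __post_init__(self):
        if self.T_max <= 0 or self.K_p <= 0:
            raise ValueError("T_max and K_p must be positive")


@dataclass
class IonotropicParams:
    g_receptor: float = 1.0   # maximal conductance (scaled per connection)
    E_receptor: float = 0.0   # mV
    alpha: float = 1.1        # 1/(mM ms)
    beta: float = 0.19        # 1/ms

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("binding rates must be positive")


@dataclass
class MetabotropicState:
    r: float = 0.0            # activated receptor fraction
    s: float = 0.0            # second-messenger concentration
    K1: float = 1.3           # 1/(mM ms)
    K2: float = 0.006         # 1/ms
    K3: float = 0.09          # 1/ms
    K4: float = 0.0064        # 1/ms
    Kd: float = 100.0
    hill_n: int = 4
    g_receptor: float = 1.0
    E_receptor: float = -95.0

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("s must be non-negative")
        if min(self.K1, self.K2, self.K3, self.K4, self.Kd) <= 0:
            raise ValueError("kinetic constants must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


def transmitter_concentration(V_pre, p: TransmitterParams):
    """T(V_pre) = T_max / (1 + exp(-(V_pre - V_t)/K_p)), in mM."""
    V_pre = np.asarray(V_pre, dtype=float)
    out = p.T_max / (1.0 + np.exp(-(V_pre - p.V_t) / p.K_p))
    return out if out.ndim else float(out)


def ionotropic_derivative(m, T, p: IonotropicParams):
    """dm/dt = alpha*T*(1-m) - beta*m."""
    return p.alpha * T * (1.0 - m) - p.beta * m


def ionotropic_step(m, T, p: IonotropicParams, dt):
    """Advance the open fraction one step (RK4) under transmitter T."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    k1 = ionotropic_derivative(m, T, p)
    k2 = ionotropic_derivative(m + 0.5 * dt * k1, T, p)
    k3 = ionotropic_derivative(m + 0.5 * dt * k2, T, p)
    k4 = ionotropic_derivative(m + dt * k3, T, p)
    m1 = m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return min(1.0, max(0.0, m1))


def ionotropic_current(m, V_post, p: IonotropicParams):
    """I = g * m * (V_post - E)."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    return p.g_receptor * m * (V_post - p.E_receptor)


def metabotropic_derivatives(state: MetabotropicState, T):
    dr = state.K1 * T * (1.0 - state.r) - state.K2 * state.r
    ds = state.K3 * state.r - state.K4 * state.s
    return dr, ds


def metabotropic_step(state: MetabotropicState, T, dt) -> MetabotropicState:
    """Advance (r, s) one RK4 step under transmitter T."""
    if dt <= 0:
        raise ValueError("dt must be positive")

    def deriv(r, s):
        return (state.K1 * T * (1.0 - r) - state.K2 * r,
                state.K3 * r - state.K4 * s)

    r, s = state.r, state.s
    k1 = deriv(r, s)
    k2 = deriv(r + 0.5 * dt * k1[0], s + 0.5 * dt * k1[1])
    k3 = deriv(r + 0.5 * dt * k2[0], s + 0.5 * dt * k2[1])
    k4 = deriv(r + dt * k3[0], s + dt * k3[1])
    r1 = r + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    s1 = s + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return MetabotropicState(
        r=min(1.0, max(0.0, r1)), s=max(0.0, s1),
        K1=state.K1, K2=state.K2, K3=state.K3, K4=state.K4,
        Kd=state.Kd, hill_n=state.hill_n,
        g_receptor=state.g_receptor, E_receptor=state.E_receptor,
    )


def hill_factor(s, Kd, n):
    """s^n / (s^n + Kd), in [0, 1)."""
    sn = float(s) ** n
    return sn / (sn + Kd)


def metabotropic_current(state: MetabotropicState, V_post):
    """I = g * s^n/(s^n + Kd) * (V_post - E)."""
    return state.g_receptor * hill_factor(state.s, state.Kd, state.hill_n) \
        * (V_post - state.E_receptor)


def ionotropic_params_from_config(receptor: str, block: dict,
                                  g: float = 1.0) -> IonotropicParams:
    if receptor not in IONOTROPIC:
        raise ValueError(f"{receptor!r} is not an ionotropic receptor")
    return IonotropicParams(g_receptor=g, E_receptor=block["E"],
                            alpha=block["alpha"], beta=block["beta"])


def metabotropic_state_from_config(receptor: str, block: dict,
                                   g: float = 1.0) -> MetabotropicState:
    if receptor not in METABOTROPIC:
        raise ValueError(f"{receptor!r} is not a metabotropic receptor")
    return MetabotropicState(K1=block["K1"], K2=block["K2"], K3=block["K3"],
                             K4=block["K4"], Kd=block["Kd"], hill_n=block["n"],
                             g_receptor=g, E_receptor=block["E"])
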