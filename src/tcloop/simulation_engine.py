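"""Fixed-step RK4 integration of the full thalamocortical network.

The whole network (membrane voltages, HH and intrinsic gates, per-projection
synaptic states) is packed into one flat state vector and advanced with a
fixed-step fourth-order Runge-Kutta scheme, by default at dt = 0.025 ms.
Transmitter concentration is the sigmoid of the presynaptic stage voltage, so
synaptic gating is integrated fully coupled with the membrane equations.

Synaptic state is carried per presynaptic neuron per projection (the standard
kinetic-synapse reduction): each presynaptic cell drives one open-fraction
trajectory, and the postsynaptic current is the projection's weight matrix
applied to those open fractions times the local driving force.

A run is deterministic: identical configuration gives bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import neuron_models as nm
from .network_builder import NetworkConfig

KIND_CODE = {"Ctx": 0, "TC": 1, "TRN": 2, "IN": 3}

SPIKE_THRESHOLD = -20.0   # mV, upward crossing
SPIKE_REFRACTORY = 2.0    # ms
BLOWUP_LIMIT = 200.0      # mV


class NumericalBlowup(RuntimeError):
    def __init__(self, neuron: int, time_ms: float):
        super().__init__(f"|V| exceeded {BLOWUP_LIMIT} mV at neuron {neuron}, "
                         f"t = {time_ms:.3f} ms")
        self.neuron = neuron
        self.time_ms = time_ms


@dataclass
class StimulusSpec:
    """Brief current pulse into one neuron (population name + local index)."""

    population: str = "TRN_core"
    index: int = 50
    amplitude: float = 3.0    # uA/cm^2
    onset: float = 500.0      # ms; a settling period precedes the pulse
    duration: float = 50.0    # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.onset < 0:
            raise ValueError("stimulus onset must be non-negative")


@dataclass
class SpikeRaster:
    """Spike events (neuron index, time in ms) for one population."""

    events: np.ndarray        # (n_events, 2): neuron local index, time ms
    n_neurons: int
    duration: float

    @property
    def neuron_indices(self) -> np.ndarray:
        return self.events[:, 0].astype(int)

    @property
    def times(self) -> np.ndarray:
        return self.events[:, 1]

    def to_csv(self) -> str:
        lines = ["neuron_id,time_ms"]
        lines += [f"{int(i)},{t:.6g}" for i, t in self.events]
        return "\n".join(lines) + "\n"


@dataclass
class SimulationResult:
    rasters: dict[str, SpikeRaster]
    traces: np.ndarray        # (n_samples, n_neurons) float32, mV
    trace_times: np.ndarray   # ms
    dt: float
    duration: float
    net: NetworkConfig = field(repr=False, default=None)

    def population_traces(self, name: str) -> np.ndarray:
        sl = self.net.population_slice(name)
        return self.traces[:, sl]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _vtrap(x, scale):
    if abs(x / scale) < 1e-6:
        return scale * (1.0 - x / (2.0 * scale))
    return x / (np.expm1(x / scale))


@njit(cache=True, fastmath=True)
def _deriv(y, dy, n, p,
           Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp, gH, EH, k2H, CH,
           kindcode, strictF,
           n_proj, edge_ptr, edge_row, edge_col, edge_val,
           is_metab, pre0, post0, Eproj, gproj, a1, a2, K3, K4, Kd, hilln,
           syn_off, Tmax, Vt, Kp, Iext):
    # currents from synapses onto each neuron (sparse edge lists per projection)
    isyn = np.zeros(n)
    gate = np.empty(p)
    for j in range(n_proj):
        off = syn_off[j]
        if is_metab[j] == 1:
            for q in range(p):
                s = y[off + p + q]
                if s < 0.0:
                    s = 0.0
                sn = s ** hilln[j]
                gate[q] = sn / (sn + Kd[j])
        else:
            for q in range(p):
                gate[q] = y[off + q]
        for k in range(edge_ptr[j], edge_ptr[j + 1]):
            i = post0[j] + edge_row[k]
            isyn[i] += gproj[j] * edge_val[k] * gate[edge_col[k]] * (y[i] - Eproj[j])

    # membrane + gating equations per neuron
    for i in range(n):
        V = y[i]
        m = y[n + i]
        h = y[2 * n + i]
        nk = y[3 * n + i]
        v2 = V - VT[i]
        am = 0.32 * _vtrap(13.0 - v2, 4.0)
        bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
        ah = 0.128 * np.exp((17.0 - v2) / 18.0)
        bh = 4.0 / (1.0 + np.exp((40.0 - v2) / 5.0))
        an = 0.032 * _vtrap(15.0 - v2, 5.0)
        bn = 0.5 * np.exp((10.0 - v2) / 40.0)
        dy[n + i] = am * (1.0 - m) - bm * m
        dy[2 * n + i] = ah * (1.0 - h) - bh * h
        dy[3 * n + i] = an * (1.0 - nk) - bn * nk

        I_Na = gNa[i] * m ** 3 * h * (V - ENa[i])
        I_K = gK[i] * nk ** 4 * (V - EK[i])
        I_L = gL[i] * (V - EL[i])
        I_int = 0.0

        kind = kindcode[i]
        if kind == 1 or kind == 2:          # TC or TRN: I_T
            mT = y[4 * n + i]
            hT = y[5 * n + i]
            if kind == 2:                   # TRN kinetics, exponent 2
                m_inf = 1.0 / (1.0 + np.exp(-(V + 52.0) / 7.4))
                h_inf = 1.0 / (1.0 + np.exp((V + 80.0) / 5.0))
                tau_m = 1.0 + 0.33 / (np.exp((V + 27.0) / 10.0)
                                      + np.exp(-(V + 102.0) / 15.0))
                tau_h = 28.3 + 0.33 / (np.exp((V + 48.0) / 4.0)
                                       + np.exp(-(V + 407.0) / 50.0))
                I_int += gCa[i] * mT * mT * hT * (V - ECa[i])
            else:                           # TC kinetics, exponent 3
                m_inf = 1.0 / (1.0 + np.exp(-(V + 57.0) / 6.2))
                h_inf = 1.0 / (1.0 + np.exp((V + 81.0) / 4.0))
                tau_m = (0.612 + 1.0 / (np.exp(-(V + 132.0) / 16.7)
                                        + np.exp((V + 16.8) / 18.2))) / 3.74
                if V < -80.0:
                    tau_h = np.exp((V + 467.0) / 66.6) / 3.73
                else:
                    tau_h = (28.0 + np.exp(-(V + 22.0) / 10.5)) / 3.73
                I_int += gCa[i] * mT * mT * mT * hT * (V - ECa[i])
            dy[4 * n + i] = (m_inf - mT) / tau_m
            dy[5 * n + i] = (h_inf - hT) / tau_h
        else:
            dy[4 * n + i] = 0.0
            dy[5 * n + i] = 0.0

        if kind == 1:                       # TC: I_H
            S1 = y[6 * n + i]
            F1 = y[7 * n + i]
            S2 = y[8 * n + i]
            F2 = y[9 * n + i]
            hH = 1.0 / (1.0 + np.exp((V + 68.9) / 6.5))
            tauS = np.exp((V + 183.6) / 15.24)
            tauF = np.exp((V + 158.6) / 11.2) / (1.0 + np.exp((V + 75.0) / 5.5))
            aS = hH / tauS
            bS = (1.0 - hH) / tauS
            aF = hH / tauF
            bF = (1.0 - hH) / tauF
            lockF = S1 if strictF == 1 else F1
            dy[6 * n + i] = aS * (1.0 - S1 - S2) - bS * S1 + k2H[i] * S2 - CH[i] * S1
            dy[7 * n + i] = aF * (1.0 - F1 - F2) - bF * F1 + k2H[i] * F2 - CH[i] * lockF
            dy[8 * n + i] = CH[i] * S1 - k2H[i] * S2
            dy[9 * n + i] = CH[i] * F1 - k2H[i] * F2
            I_int += gH[i] * (S1 + S2) * (F1 + F2) * (V - EH[i])
        else:
            dy[6 * n + i] = 0.0
            dy[7 * n + i] = 0.0
            dy[8 * n + i] = 0.0
            dy[9 * n + i] = 0.0

        dy[i] = (-I_L - I_Na - I_K - I_int - isyn[i] + Iext[i]) / Cm[i]

    # synaptic state equations, driven by presynaptic voltage
    for j in range(n_proj):
        off = syn_off[j]
        for q in range(p):
            Vpre = y[pre0[j] + q]
            T = Tmax / (1.0 + np.exp(-(Vpre - Vt) / Kp))
            if is_metab[j] == 1:
                r = y[off + q]
                s = y[off + p + q]
                dy[off + q] = a1[j] * T * (1.0 - r) - a2[j] * r
                dy[off + p + q] = K3[j] * r - K4[j] * s
            else:
                mrec = y[off + q]
                dy[off + q] = a1[j] * T * (1.0 - mrec) - a2[j] * mrec


@njit(cache=True)
def _run(y0, n, p, nsteps, dt, stride,
         Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp, gH, EH, k2H, CH,
         kindcode, strictF,
         n_proj, edge_ptr, edge_row, edge_col, edge_val,
         is_metab, pre0, post0, Eproj, gproj, a1, a2, K3, K4, Kd, hilln,
         syn_off, Tmax, Vt, Kp,
         stim_idx, stim_amp, stim_on_step, stim_off_step,
         thr, refr, max_spikes):
    # stim_* are parallel arrays: one entry per stimulated neuron
    y = y0.copy()
    dy1 = np.empty_like(y)
    dy2 = np.empty_like(y)
    dy3 = np.empty_like(y)
    dy4 = np.empty_like(y)
    Iext = np.zeros(n)

    n_rec = nsteps // stride + 1
    traces = np.empty((n_rec, n), dtype=np.float32)
    traces[0] = y[:n].astype(np.float32)

    spike_idx = np.empty(max_spikes, dtype=np.int64)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    n_spk = 0
    last_spike = np.full(n, -1e9)
    prev_V = y[:n].copy()

    err_neuron = -1
    err_time = -1.0

    for step in range(nsteps):
        for si in range(len(stim_idx)):
            if stim_on_step[si] <= step < stim_off_step[si]:
                Iext[stim_idx[si]] = stim_amp[si]
            else:
                Iext[stim_idx[si]] = 0.0

        _deriv(y, dy1, n, p, Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp,
               gH, EH, k2H, CH, kindcode, strictF, n_proj, edge_ptr, edge_row,
               edge_col, edge_val, is_metab, pre0, post0,
               Eproj, gproj, a1, a2, K3, K4, Kd, hilln, syn_off, Tmax, Vt, Kp, Iext)
        yt = y + 0.5 * dt * dy1
        _deriv(yt, dy2, n, p, Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp,
               gH, EH, k2H, CH, kindcode, strictF, n_proj, edge_ptr, edge_row,
               edge_col, edge_val, is_metab, pre0, post0,
               Eproj, gproj, a1, a2, K3, K4, Kd, hilln, syn_off, Tmax, Vt, Kp, Iext)
        yt = y + 0.5 * dt * dy2
        _deriv(yt, dy3, n, p, Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp,
               gH, EH, k2H, CH, kindcode, strictF, n_proj, edge_ptr, edge_row,
               edge_col, edge_val, is_metab, pre0, post0,
               Eproj, gproj, a1, a2, K3, K4, Kd, hilln, syn_off, Tmax, Vt, Kp, Iext)
        yt = y + dt * dy3
        _deriv(yt, dy4, n, p, Cm, gL, EL, gNa, ENa, gK, EK, VT, gCa, ECa, texp,
               gH, EH, k2H, CH, kindcode, strictF, n_proj, edge_ptr, edge_row,
               edge_col, edge_val, is_metab, pre0, post0,
               Eproj, gproj, a1, a2, K3, K4, Kd, hilln, syn_off, Tmax, Vt, Kp, Iext)
        y += (dt / 6.0) * (dy1 + 2.0 * dy2 + 2.0 * dy3 + dy4)

        t = (step + 1) * dt
        for i in range(n):
            V = y[i]
            if abs(V) > BLOWUP_LIMIT:
                err_neuron = i
                err_time = t
                break
            if V >= thr and prev_V[i] < thr and t - last_spike[i] >= refr:
                if n_spk < max_spikes:
                    spike_idx[n_spk] = i
                    spike_t[n_spk] = t
                    n_spk += 1
                last_spike[i] = t
            prev_V[i] = V
        if err_neuron >= 0:
            break
        if (step + 1) % stride == 0:
            traces[(step + 1) // stride] = y[:n].astype(np.float32)

    return (traces, spike_idx[:n_spk], spike_t[:n_spk],
            err_neuron, err_time, y)


# ---------------------------------------------------------------------------
# assembly + public API
# ---------------------------------------------------------------------------

def _pack(net: NetworkConfig):
    """Flatten a NetworkConfig into the kernel's parameter arrays."""
    params = net.params
    species = params["neurons"][net.species]
    pops = net.populations
    p = pops[0].size
    n = net.n_neurons

    def arr(key, default=0.0):
        out = np.full(n, default)
        for pop in pops:
            sl = net.population_slice(pop.name)
            out[sl] = species[pop.kind].get(key, default)
        return out

    Cm, gL, EL = arr("Cm", 1.0), arr("g_leak"), arr("E_leak", -70.0)
    gNa, ENa = arr("g_Na"), arr("E_Na", 50.0)
    gK, EK = arr("g_K"), arr("E_K", -90.0)
    VT = arr("V_T", -55.0)
    gCa, ECa = arr("g_Ca"), arr("E_Ca", 120.0)
    gH, EH = arr("g_H"), arr("E_H", -43.0)
    k2H, CH = arr("k2", 4e-4), arr("C", 2e-4)
    texp = np.zeros(n, dtype=np.int64)
    kindcode = np.zeros(n, dtype=np.int64)
    for pop in pops:
        sl = net.population_slice(pop.name)
        kindcode[sl] = KIND_CODE[pop.kind]
        if pop.kind == "TRN":
            texp[sl] = 2
        elif pop.kind == "TC":
            texp[sl] = 3

    conns = net.connections
    n_proj = len(conns)
    edge_ptr = np.zeros(n_proj + 1, dtype=np.int64)
    rows, cols, vals = [], [], []
    for j, c in enumerate(conns):
        r, cidx = np.nonzero(c.matrix)
        rows.append(r)
        cols.append(cidx)
        vals.append(c.matrix[r, cidx])
        edge_ptr[j + 1] = edge_ptr[j] + len(r)
    edge_row = np.concatenate(rows).astype(np.int64) if rows else np.zeros(0, np.int64)
    edge_col = np.concatenate(cols).astype(np.int64) if cols else np.zeros(0, np.int64)
    edge_val = np.concatenate(vals) if vals else np.zeros(0)
    is_metab = np.zeros(n_proj, dtype=np.int64)
    pre0 = np.zeros(n_proj, dtype=np.int64)
    post0 = np.zeros(n_proj, dtype=np.int64)
    Eproj = np.zeros(n_proj)
    gproj = np.zeros(n_proj)
    a1 = np.zeros(n_proj)
    a2 = np.zeros(n_proj)
    K3 = np.zeros(n_proj)
    K4 = np.zeros(n_proj)
    Kd = np.ones(n_proj)
    hilln = np.ones(n_proj)
    syn_off = np.zeros(n_proj, dtype=np.int64)

    syn = params["synapses"]
    offset = 10 * n
    for j, c in enumerate(conns):
        pre0[j] = net.population_slice(c.source).start
        post0[j] = net.population_slice(c.target).start
        gproj[j] = c.weight
        block = syn[c.receptor]
        Eproj[j] = block["E"]
        syn_off[j] = offset
        if c.is_metabotropic:
            is_metab[j] = 1
            a1[j], a2[j] = block["K1"], block["K2"]
            K3[j], K4[j] = block["K3"], block["K4"]
            Kd[j], hilln[j] = block["Kd"], float(block["n"])
            offset += 2 * p
        else:
            a1[j], a2[j] = block["alpha"], block["beta"]
            offset += p

    tr = params["transmitter"]
    return dict(n=n, p=p, state_size=offset,
                Cm=Cm, gL=gL, EL=EL, gNa=gNa, ENa=ENa, gK=gK, EK=EK, VT=VT,
                gCa=gCa, ECa=ECa, texp=texp, gH=gH, EH=EH, k2H=k2H, CH=CH,
                kindcode=kindcode,
                n_proj=n_proj, edge_ptr=edge_ptr, edge_row=edge_row,
                edge_col=edge_col, edge_val=edge_val,
                is_metab=is_metab, pre0=pre0, post0=post0, Eproj=Eproj,
                gproj=gproj, a1=a1, a2=a2, K3=K3, K4=K4, Kd=Kd, hilln=hilln,
                syn_off=syn_off,
                Tmax=tr["T_max"], Vt=tr["V_t"], Kp=tr["K_p"])


def initial_state(net: NetworkConfig) -> np.ndarray:
    """Every neuron at its isolated resting potential, gates at steady state."""
    pk = _pack(net)
    n = pk["n"]
    y = np.zeros(pk["state_size"])
    species = net.params["neurons"][net.species]
    cache: dict[str, nm.NeuronState] = {}
    for pop in net.populations:
        if pop.kind not in cache:
            block = species[pop.kind]
            mp = nm.membrane_params_from_config(block)
            tp = hp = None
            if pop.kind in ("TC", "TRN"):
                tp = nm.TCurrentParams(g_Ca=block["g_Ca"], E_Ca=block["E_Ca"],
                                       activation_exponent=2 if pop.kind == "TRN" else 3)
            if pop.kind == "TC":
                hp = nm.HCurrentParams(g_H=block["g_H"], E_H=block["E_H"],
                                       k2=block["k2"], C=block["C"])
            cache[pop.kind] = nm.resting_state(pop.kind, mp, tp, hp)
        st = cache[pop.kind]
        sl = net.population_slice(pop.name)
        y[sl] = st.V
        y[n + sl.start:n + sl.stop] = st.hh.m
        y[2 * n + sl.start:2 * n + sl.stop] = st.hh.h
        y[3 * n + sl.start:3 * n + sl.stop] = st.hh.n
        if st.t_gate is not None:
            y[4 * n + sl.start:4 * n + sl.stop] = st.t_gate[0]
            y[5 * n + sl.start:5 * n + sl.stop] = st.t_gate[1]
        if st.h_state is not None:
            y[6 * n + sl.start:6 * n + sl.stop] = st.h_state.S1
            y[7 * n + sl.start:7 * n + sl.stop] = st.h_state.F1
            y[8 * n + sl.start:8 * n + sl.stop] = st.h_state.S2
            y[9 * n + sl.start:9 * n + sl.stop] = st.h_state.F2
    return y


def default_stimulus(net: NetworkConfig) -> list[StimulusSpec]:
    """Initiation pulses: the center TRN neuron of each circuit.

    Each circuit is initiated through its own reticular nucleus because the
    only inter-circuit pathway is the one-to-one cortico-cortical mixing,
    which carries ongoing activity but not the initial ignition.
    """
    mid = net.populations[0].size // 2
    return [StimulusSpec("TRN_core", mid), StimulusSpec("TRN_matrix", mid)]


def simulate(net: NetworkConfig, stim: StimulusSpec | list | None = None,
             duration: float = 7000.0, dt: float = 0.025,
             trace_stride_ms: float = 1.0,
             spike_threshold: float = SPIKE_THRESHOLD,
             refractory: float = SPIKE_REFRACTORY,
             strict_printed_h_current: bool = False,
             y0: np.ndarray | None = None) -> SimulationResult:
    """Integrate the network and return per-population rasters and traces."""
    if not 0.0 < dt <= 0.05:
        raise ValueError("dt must lie in (0, 0.05] ms")
    if stim is None:
        stim = default_stimulus(net)

    pk = _pack(net)
    if y0 is None:
        y0 = initial_state(net)
    nsteps = int(round(duration / dt))
    stride = max(1, int(round(trace_stride_ms / dt)))
    stims = stim if isinstance(stim, (list, tuple)) else [stim]
    if duration < max(s.onset + s.duration for s in stims):
        raise ValueError("duration must cover every stimulus")
    stim_idx = np.array([net.population_slice(s.population).start + s.index
                         for s in stims], dtype=np.int64)
    stim_amp = np.array([s.amplitude for s in stims])
    on_step = np.array([int(round(s.onset / dt)) for s in stims], dtype=np.int64)
    off_step = np.array([int(round((s.onset + s.duration) / dt)) for s in stims],
                        dtype=np.int64)
    max_spikes = int(pk["n"] * duration * 0.5) + 1000

    traces, sidx, st, err_neuron, err_time, _ = _run(
        y0, pk["n"], pk["p"], nsteps, dt, stride,
        pk["Cm"], pk["gL"], pk["EL"], pk["gNa"], pk["ENa"], pk["gK"], pk["EK"],
        pk["VT"], pk["gCa"], pk["ECa"], pk["texp"], pk["gH"], pk["EH"],
        pk["k2H"], pk["CH"], pk["kindcode"],
        1 if strict_printed_h_current else 0,
        pk["n_proj"], pk["edge_ptr"], pk["edge_row"], pk["edge_col"],
        pk["edge_val"], pk["is_metab"], pk["pre0"], pk["post0"], pk["Eproj"],
        pk["gproj"], pk["a1"], pk["a2"], pk["K3"], pk["K4"], pk["Kd"],
        pk["hilln"], pk["syn_off"], pk["Tmax"], pk["Vt"], pk["Kp"],
        stim_idx, stim_amp, on_step, off_step,
        spike_threshold, refractory, max_spikes)

    if err_neuron >= 0:
        raise NumericalBlowup(err_neuron, err_time)

    rasters = {}
    for pop in net.populations:
        sl = net.population_slice(pop.name)
        mask = (sidx >= sl.start) & (sidx < sl.stop)
        ev = np.column_stack([(sidx[mask] - sl.start).astype(float), st[mask]])
        order = np.lexsort((ev[:, 1], ev[:, 0])) if len(ev) else np.array([], dtype=int)
        rasters[pop.name] = SpikeRaster(events=ev[order], n_neurons=pop.size,
                                        duration=duration)
    trace_times = np.arange(traces.shape[0]) * stride * dt
    return SimulationResult(rasters=rasters, traces=traces,
                            trace_times=trace_times, dt=dt, duration=duration,
                            net=net)


def detect_spikes(trace: np.ndarray, times: np.ndarray | None = None,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY,
                  dt: float = 1.0) -> np.ndarray:
    """Upward threshold crossings separated by >= refractory, on the trace grid."""
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    trace = np.asarray(trace, dtype=float)
    if times is None:
        times = np.arange(len(trace)) * dt
    crossings = np.flatnonzero((trace[1:] >= threshold) & (trace[:-1] < threshold)) + 1
    out = []
    last = -np.inf
    for k in crossings:
        t = times[k]
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)


def run_cube(build, vertices, stim: StimulusSpec | None = None,
             duration: float = 7000.0, dt: float = 0.025, **kwargs):
    """One simulation per cube vertex; per-vertex failures do not halt the sweep.

    ``build`` is a callable CubePoint -> NetworkConfig.  Returns a dict keyed
    by the cube coordinates, with either a SimulationResult or the exception.
    """
    vertices = list(vertices)
    if not vertices:
        raise ValueError("need at least one cube vertex")
    out = {}
    for v in vertices:
        key = (v.core_tc_strength, v.matrix_tc_strength, v.cc_mixing_strength)
        try:
            out[key] = simulate(build(v), stim, duration, dt, **kwargs)
        except (NumericalBlowup, ValueError) as exc:
            out[key] = exc
    return out
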