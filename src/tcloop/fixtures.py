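"""Synthetic rasters and signals with known ground truth.

These generators emulate the geometries the analysis suite must recover --
vertical and tilted activity bands, mirror-symmetric boomerang bands, and
amplitude-modulated sigma-band oscillations -- so every metric can be tested
against closed-form truth without running the biophysical simulator.  Output
containers are the same SpikeRaster / AveragedSignal types the simulator
emits, so fixtures and real runs are interchangeable analysis inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulation_engine import SpikeRaster
from .spindle_analysis import AveragedSignal


@dataclass
class BandSpec:
    """One activity band: a volley with per-neuron lag and optional jitter."""

    center_time: float            # ms
    n_neurons: int = 50
    lag_per_neuron: float = 0.0   # ms tilt per neuron index step
    jitter_sd: float = 0.0        # ms
    shape: str = "linear"         # linear | boomerang
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.shape not in ("linear", "boomerang"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def spike_times(self) -> np.ndarray:
        """Ground-truth spike time per neuron index (before jitter)."""
        i = np.arange(self.n_neurons, dtype=float)
        if self.shape == "linear":
            lag = self.lag_per_neuron * (i - (self.n_neurons - 1) / 2.0)
        else:
            # exact mirror about the center neuron: lag grows with distance
            lag = self.lag_per_neuron * np.abs(i - (self.n_neurons - 1) / 2.0)
            lag -= lag.mean()
        return self.center_time + lag

    @property
    def half_width(self) -> float:
        span = abs(self.lag_per_neuron) * (self.n_neurons - 1) / 2.0
        return span + 6.0 * self.jitter_sd + 5.0


@dataclass
class BurstSpec:
    """One spindle-like burst: a Gaussian-enveloped sigma-band carrier."""

    center_time: float            # s
    carrier_hz: float = 11.0
    envelope_sd: float = 0.15     # s
    peak_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 8.0 <= self.carrier_hz <= 20.0:
            raise ValueError("carrier must lie in the 8-20 Hz analysis band")


def synth_raster(bands: list[BandSpec], n_neurons: int,
                 duration: float) -> SpikeRaster:
    """Raster realizing the given bands; identical seeds give identical output."""
    windows = []
    events = []
    for spec in bands:
        if spec.n_neurons > n_neurons:
            raise ValueError("band wider than raster")
        t0 = spec.center_time - spec.half_width
        t1 = spec.center_time + spec.half_width
        if t0 < 0 or t1 > duration:
            raise ValueError("band window outside raster duration")
        for w0, w1 in windows:
            if t0 < w1 and w0 < t1:
                raise ValueError("overlapping bands make ground truth ambiguous")
        windows.append((t0, t1))
        rng = np.random.default_rng(spec.seed)
        times = spec.spike_times()
        if spec.jitter_sd > 0:
            times = times + rng.normal(0.0, spec.jitter_sd, size=len(times))
        idx = np.arange(spec.n_neurons, dtype=float)
        events.append(np.column_stack([idx, times]))
    ev = (np.concatenate(events) if events
          else np.zeros((0, 2)))
    order = np.lexsort((ev[:, 1], ev[:, 0])) if len(ev) else []
    return SpikeRaster(events=ev[order] if len(ev) else ev,
                       n_neurons=n_neurons, duration=duration)


def synth_signal(bursts: list[BurstSpec], noise_sd: float = 0.0,
                 duration: float = 7.0, rate: float = 1.0,
                 seed: int = 0) -> AveragedSignal:
    """Sum of enveloped sinusoids plus seeded white noise.

    ``duration`` in seconds, ``rate`` in samples per ms (so 1.0 -> 1 kHz).
    """
    fs_hz = rate * 1000.0
    if bursts and fs_hz < 2.0 * max(b.carrier_hz for b in bursts):
        raise ValueError("sampling rate below Nyquist for a burst carrier")
    t = np.arange(int(round(duration * 1000.0 * rate))) / (1000.0 * rate)  # s
    x = np.zeros_like(t)
    for b in bursts:
        env = b.peak_amplitude * np.exp(-0.5 * ((t - b.center_time) / b.envelope_sd) ** 2)
        x += env * np.cos(2.0 * np.pi * b.carrier_hz * (t - b.center_time))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    return AveragedSignal(samples=x, rate=rate, label="mixed", source=None)
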