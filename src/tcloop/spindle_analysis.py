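"""Sleep-spindle detection and spectral analysis.

Spindle proxy signals are built by averaging the membrane voltage of small
cortical neuron groups: five core neurons, five matrix neurons, or ten mixed
(5 + 5).  The average is bandpass filtered in the sigma band (9-13 Hz,
zero-phase Butterworth) and the analytic-signal envelope extracted.  Spindle
events are envelope peaks that exceed 30 % of the largest peak and are at
least 0.5 s from any larger accepted peak; each event's duration is the time
between the envelope local minima flanking its peak.  Density is the number
of accepted events per trace.

The spectral view is a periodogram of the averaged signal reported in the
8-20 Hz window, log-displayable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats


@dataclass
class AveragedSignal:
    samples: np.ndarray       # mV
    rate: float               # samples per ms
    label: str = "core"       # core | matrix | mixed
    source: list | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass
class SpindleEvent:
    peak_time: float          # ms
    amplitude: float          # envelope units
    duration: float           # ms, between flanking envelope minima
    passes_threshold: bool = True


@dataclass
class SpectralDensity:
    freqs: np.ndarray         # Hz
    power: np.ndarray
    band: tuple = (8.0, 20.0)


GROUP_SIZES = {"core": 5, "matrix": 5, "mixed": 10}


def average_activity(traces: np.ndarray, group: list[int], label: str = "core",
                     rate: float = 1.0) -> AveragedSignal:
    """Pointwise mean of the selected neuron columns of a trace array."""
    expected = GROUP_SIZES.get(label)
    if expected is not None and len(group) != expected:
        raise ValueError(f"{label} group must have {expected} neurons, "
                         f"got {len(group)}")
    sel = np.asarray(traces, dtype=float)[:, list(group)]
    return AveragedSignal(samples=sel.mean(axis=1), rate=rate, label=label,
                          source=list(group))


def bandpass(sig: AveragedSignal, lo: float = 9.0, hi: float = 13.0,
             order: int = 4) -> AveragedSignal:
    """Zero-phase Butterworth bandpass; frequencies in Hz, rate in samples/ms."""
    fs_hz = sig.rate * 1000.0
    if fs_hz < 2.0 * hi:
        raise ValueError("sampling rate below Nyquist for the passband")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples - sig.samples.mean())
    return AveragedSignal(samples=filtered, rate=sig.rate,
                          label=sig.label, source=sig.source)


def envelope(sig: AveragedSignal) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal."""
    return np.abs(sps.hilbert(sig.samples))


def detect_spindles(filtered: AveragedSignal, threshold_frac: float = 0.30,
                    min_separation_ms: float = 500.0,
                    use_envelope: bool = True) -> tuple[list[SpindleEvent], int]:
    """Detect spindle events on the filtered trace; returns (events, density).

    Candidate peaks are local maxima of the envelope (or of the raw filtered
    oscillation).  A peak is kept if its amplitude is at least
    ``threshold_frac`` of the largest peak and it is not within
    ``min_separation_ms`` of an already-accepted larger peak (greedy by
    descending amplitude).  Duration is the gap between the local minima
    flanking the peak.
    """
    x = envelope(filtered) if use_envelope else np.abs(filtered.samples)
    if len(x) == 0 or not np.any(x > 0):
        return [], 0
    dt = 1.0 / filtered.rate  # ms per sample

    peaks, _ = sps.find_peaks(x)
    if len(peaks) == 0:
        return [], 0
    amp_max = x[peaks].max()
    thr = threshold_frac * amp_max

    minima, _ = sps.find_peaks(-x)

    accepted: list[int] = []
    for k in peaks[np.argsort(x[peaks])[::-1]]:
        if x[k] < thr:
            break
        if all(abs(k - a) * dt >= min_separation_ms for a in accepted):
            accepted.append(k)
    accepted.sort()

    events = []
    for k in accepted:
        left = minima[minima < k]
        right = minima[minima > k]
        lo_i = left[-1] if len(left) else 0
        hi_i = right[0] if len(right) else len(x) - 1
        events.append(SpindleEvent(peak_time=k * dt, amplitude=float(x[k]),
                                   duration=(hi_i - lo_i) * dt))
    return events, len(events)


def compute_psd(sig: AveragedSignal, band: tuple = (8.0, 20.0),
                min_duration_ms: float = 2000.0) -> SpectralDensity:
    """Periodogram of the averaged signal, restricted to the reporting band."""
    n = len(sig.samples)
    if n / sig.rate < min_duration_ms:
        raise ValueError("signal too short for spectral analysis")
    fs_hz = sig.rate * 1000.0
    freqs, power = sps.periodogram(sig.samples - sig.samples.mean(), fs=fs_hz)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return SpectralDensity(freqs=freqs[mask], power=power[mask], band=band)


def kruskal_wallis(*groups):
    """Kruskal-Wallis H and p for >= 2 groups of metric values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("groups must be non-empty")
    H, p = spstats.kruskal(*groups)
    return float(H), float(p)


def spindle_events_csv(events: list[SpindleEvent]) -> str:
    buf = io.StringIO()
    buf.write("peak_time_ms,amplitude,duration_ms\n")
    for e in events:
        buf.write(f"{e.peak_time:.3f},{e.amplitude:.6g},{e.duration:.3f}\n")
    return buf.getvalue()


def spindle_metrics(traces: np.ndarray, rate: float, core_group: list[int],
                    matrix_group: list[int] | None = None,
                    label: str = "core", lo: float = 9.0, hi: float = 13.0,
                    **detect_kwargs) -> dict:
    """End-to-end spindle metrics for one neuron group.

    For ``label='mixed'`` both 5-neuron groups are required and averaged
    together (10 neurons).  Returns amplitudes, durations and density.
    """
    if label == "mixed":
        if matrix_group is None:
            raise ValueError("mixed label requires both groups")
        group = list(core_group) + list(matrix_group)
    else:
        group = list(core_group)
    avg = average_activity(traces, group, label=label, rate=rate)
    filt = bandpass(avg, lo, hi)
    events, density = detect_spindles(filt, **detect_kwargs)
    return {
        "label": label,
        "amplitudes": [e.amplitude for e in events],
        "durations": [e.duration for e in events],
        "density": density,
        "events": events,
    }
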