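"""Tests for averaging, sigma-band filtering, spindle detection, PSD and KW."""

import numpy as np
import pytest
from scipy.signal import hilbert

from tcloop import spindle_analysis as sa
from tcloop.fixtures import BurstSpec, synth_signal


def tone(freq_hz, duration_s=7.0, rate=1.0, amplitude=1.0):
    t = np.arange(int(duration_s * 1000 * rate)) / (1000.0 * rate)
    return sa.AveragedSignal(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                             rate=rate, label="core")


class TestAveraging:
    def test_identical_traces_average_to_themselves(self):
        tr = np.tile(np.sin(np.linspace(0, 10, 500))[:, None], (1, 5))
        avg = sa.average_activity(tr, [0, 1, 2, 3, 4], label="core")
        assert np.allclose(avg.samples, tr[:, 0])

    def test_constant_traces(self):
        tr = np.ones((100, 5)) * np.array([1, 2, 3, 4, 5])
        avg = sa.average_activity(tr, [0, 1, 2, 3, 4], label="core")
        assert np.allclose(avg.samples, 3.0)

    def test_mixed_group_equals_mean_of_group_means(self):
        rng = np.random.default_rng(0)
        tr = rng.normal(size=(200, 10))
        core, matrix = [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
        mixed = sa.average_activity(tr, core + matrix, label="mixed")
        m_core = sa.average_activity(tr, core, label="core")
        m_mat = sa.average_activity(tr, matrix, label="matrix")
        assert np.allclose(mixed.samples,
                           0.5 * (m_core.samples + m_mat.samples))

    def test_wrong_group_size_rejected(self):
        with pytest.raises(ValueError):
            sa.average_activity(np.zeros((10, 6)), [0, 1, 2], label="core")


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = sa.bandpass(tone(11.0))
        mid = out.samples[2000:-2000]
        # zero-phase Butterworth: unit passband gain up to numerical overshoot
        assert 0.9 <= np.abs(mid).max() <= 1.0 + 1e-3

    def test_dc_rejected(self):
        sig = sa.AveragedSignal(samples=np.ones(7000) * 5.0, rate=1.0)
        out = sa.bandpass(sig)
        assert np.abs(out.samples).max() < 0.01

    def test_stopband_tone_attenuated(self):
        out = sa.bandpass(tone(25.0))
        assert np.abs(out.samples[2000:-2000]).max() < 0.1

    def test_zero_phase(self):
        """A passband burst's envelope peak must not be delayed."""
        sig = synth_signal([BurstSpec(3.0, 11.0, 0.3, 1.0)], duration=7.0)
        out = sa.bandpass(sig)
        env = np.abs(hilbert(out.samples))
        assert abs(env.argmax() / 1000.0 - 3.0) < 0.05

    def test_nyquist_violation_rejected(self):
        sig = sa.AveragedSignal(samples=np.zeros(100), rate=0.02)  # 20 Hz fs
        with pytest.raises(ValueError):
            sa.bandpass(sig)


def brute_force_spindles(x, dt_ms, threshold_frac=0.30, min_sep_ms=500.0):
    """Exhaustive envelope-scan oracle: all local maxima, greedy selection."""
    peaks = [k for k in range(1, len(x) - 1) if x[k - 1] < x[k] >= x[k + 1]]
    peaks.sort(key=lambda k: -x[k])
    amp_max = x[peaks[0]] if peaks else 0.0
    kept = []
    for k in peaks:
        if x[k] < threshold_frac * amp_max:
            continue
        if all(abs(k - j) * dt_ms >= min_sep_ms for j in kept):
            kept.append(k)
    return sorted(kept)


class TestSpindleDetection:
    def test_zero_signal_no_events(self):
        sig = sa.AveragedSignal(samples=np.zeros(7000), rate=1.0)
        events, density = sa.detect_spindles(sig)
        assert events == [] and density == 0

    def test_three_burst_fixture_against_oracle(self):
        """Bursts with envelope peaks 1.0/0.5/0.2: the 0.2 burst fails the
        30 % rule, so exactly two events; positions match the brute-force
        envelope scan."""
        sig = synth_signal([BurstSpec(1.0, 11.0, 0.15, 1.0),
                            BurstSpec(3.0, 11.0, 0.15, 0.5),
                            BurstSpec(5.0, 11.0, 0.15, 0.2)], duration=7.0)
        filt = sa.bandpass(sig)
        events, density = sa.detect_spindles(filt)
        assert density == 2
        env = sa.envelope(filt)
        oracle = brute_force_spindles(env, 1.0)
        got = sorted(round(e.peak_time) for e in events)
        assert got == [round(k * 1.0) for k in oracle]
        assert abs(events[0].peak_time - 1000.0) < 100.0
        assert abs(events[1].peak_time - 3000.0) < 100.0

    def test_separation_rule(self):
        """Two equal bursts 0.3 s apart collapse to one event."""
        sig = synth_signal([BurstSpec(3.0, 11.0, 0.05, 1.0),
                            BurstSpec(3.3, 11.0, 0.05, 1.0)], duration=7.0)
        filt = sa.bandpass(sig)
        _, density = sa.detect_spindles(filt)
        assert density == 1

    def test_scale_invariance(self):
        sig = synth_signal([BurstSpec(1.5, 11.0, 0.15, 1.0),
                            BurstSpec(4.0, 11.0, 0.15, 0.6)], duration=7.0)
        filt = sa.bandpass(sig)
        ev1, d1 = sa.detect_spindles(filt)
        scaled = sa.AveragedSignal(samples=filt.samples * 37.0, rate=filt.rate)
        ev2, d2 = sa.detect_spindles(scaled)
        assert d1 == d2
        assert [e.peak_time for e in ev1] == [e.peak_time for e in ev2]

    def test_density_non_increasing_with_separation_window(self):
        sig = synth_signal([BurstSpec(t, 11.0, 0.1, 1.0)
                            for t in (1.0, 1.8, 2.6, 3.4, 4.2, 5.0)],
                           duration=7.0)
        filt = sa.bandpass(sig)
        densities = [sa.detect_spindles(filt, min_separation_ms=sep)[1]
                     for sep in (200.0, 500.0, 900.0, 2000.0)]
        assert all(a >= b for a, b in zip(densities, densities[1:]))

    @pytest.mark.parametrize("k", [1, 3, 5, 8])
    def test_planted_burst_recovery(self, k):
        """K well-separated suprathreshold bursts -> exactly K events."""
        centers = np.linspace(1.0, 6.0, k)
        sig = synth_signal([BurstSpec(c, 11.0, 0.08, 1.0) for c in centers],
                           duration=7.0)
        filt = sa.bandpass(sig)
        _, density = sa.detect_spindles(filt)
        assert density == k

    def test_duration_positive_and_brackets_peak(self):
        sig = synth_signal([BurstSpec(3.0, 11.0, 0.2, 1.0)], duration=7.0)
        events, _ = sa.detect_spindles(sa.bandpass(sig))
        assert len(events) == 1
        assert events[0].duration > 0


class TestPSD:
    def test_single_tone_peak_location(self):
        psd = sa.compute_psd(tone(11.0))
        assert abs(psd.freqs[np.argmax(psd.power)] - 11.0) < 0.2

    def test_two_tone_peaks(self):
        t = np.arange(7000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 14 * t)
        psd = sa.compute_psd(sa.AveragedSignal(samples=x, rate=1.0))
        order = np.argsort(psd.power)[::-1][:2]
        found = sorted(psd.freqs[order])
        assert abs(found[0] - 10.0) < 0.2 and abs(found[1] - 14.0) < 0.2

    def test_band_restricted_to_8_20(self):
        psd = sa.compute_psd(tone(11.0))
        assert psd.freqs.min() >= 8.0 and psd.freqs.max() <= 20.0
        assert np.all(np.diff(psd.freqs) > 0)
        assert np.all(psd.power >= 0)

    def test_white_noise_flatness(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=70000)
        psd = sa.compute_psd(sa.AveragedSignal(samples=x, rate=10.0))
        # average adjacent bins to tame periodogram variance
        nb = len(psd.power) // 20
        binned = psd.power[:nb * 20].reshape(nb, 20).mean(axis=1)
        assert binned.max() < 5.0 * np.median(binned)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sa.compute_psd(sa.AveragedSignal(samples=np.zeros(500), rate=1.0))


def kruskal_oracle(*groups):
    """Direct rank-formula H with tie correction."""
    all_vals = np.concatenate(groups)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(len(all_vals))
    sorted_vals = all_vals[order]
    i = 0
    r = np.arange(1, len(all_vals) + 1, dtype=float)
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        r[i:j] = r[i:j].mean()
        i = j
    ranks[order] = r
    N = len(all_vals)
    H = 0.0
    start = 0
    for g in groups:
        rg = ranks[start:start + len(g)]
        H += rg.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    denom = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    return H / denom


class TestKruskalWallis:
    def test_matches_rank_formula_oracle(self):
        g = ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
        H, p = sa.kruskal_wallis(*g)
        assert H == pytest.approx(kruskal_oracle(*g), abs=1e-10)
        assert 0.0 < p < 1.0

    def test_with_ties_matches_oracle(self):
        g = ([1.0, 1.0, 2.0, 5.0], [2.0, 2.0, 3.0], [1.0, 4.0, 4.0, 4.0])
        H, _ = sa.kruskal_wallis(*g)
        assert H == pytest.approx(kruskal_oracle(*g), abs=1e-10)

    def test_order_invariance(self):
        a, b = [3.0, 1.0, 2.0], [5.0, 6.0, 4.0]
        H1, _ = sa.kruskal_wallis(a, b)
        H2, _ = sa.kruskal_wallis(sorted(a), sorted(b))
        assert H1 == pytest.approx(H2)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            sa.kruskal_wallis([1.0, 2.0])
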