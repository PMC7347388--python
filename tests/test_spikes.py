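"""Spike detector: filtering, DTW, template estimation, detection, onsets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dtw_reference
from flymotor.spikes import (
    SpikeDetectParams,
    detect_spikes,
    dtw_distance,
    estimate_template,
    locate_onset,
    match_spike_trains,
    preprocess,
)


def _sine_response(freq, params, n=50_000):
    t = np.arange(n) / params.fs
    out = preprocess(np.sin(2 * np.pi * freq * t), params)
    return np.abs(out[n // 2 :]).max()  # skip the causal transient


class TestPreprocess:
    def test_constant_trace_maps_to_zero(self):
        params = SpikeDetectParams()
        out = preprocess(np.full(50_000, 3.7), params)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_band_pass_behavior(self):
        """In-band 500 Hz beats both 20 Hz and 5 kHz inputs."""
        params = SpikeDetectParams()
        mid = _sine_response(500.0, params)
        low = _sine_response(20.0, params)
        high = _sine_response(5000.0, params)
        assert mid > low and mid > high

    def test_linear_ramp_decays_to_zero(self):
        params = SpikeDetectParams()
        out = preprocess(np.linspace(0, 10, 50_000), params)
        assert np.abs(out[-1000:]).max() < 1e-6

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            SpikeDetectParams(fs=1000.0, hp_cutoff=209.0, lp_cutoff=898.0)


class TestDTW:
    def test_identical_segments_zero(self):
        a = np.sin(np.linspace(0, 6, 64))
        assert dtw_distance(a, a) == 0.0

    def test_time_shift_absorbed(self):
        rng = np.random.default_rng(2)
        base = np.exp(-0.5 * ((np.arange(64) - 32) / 4.0) ** 2)
        shifted = np.roll(base, 5)
        euclid = float(np.sum((base - shifted) ** 2))
        assert dtw_distance(base, shifted) < 0.1 * euclid

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 65))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            assert dtw_distance(a, b) == dtw_reference(a, b)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_axioms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        a, b = rng.normal(size=n), rng.normal(size=n)
        dab = dtw_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(dtw_distance(b, a), abs=1e-12)
        assert dtw_distance(a, a) <= 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.zeros(10), np.zeros(11))


class TestTemplate:
    def test_identical_events_reproduced(self):
        wf = np.sin(np.linspace(0, np.pi, 251))
        f = np.zeros(251 * 40)
        seeds = np.arange(5) * 2000 + 1000
        for s in seeds:
            f[s - 125 : s + 126] = wf
        tmpl = estimate_template(f, seeds, 251)
        assert np.allclose(tmpl, wf)

    def test_averaging_beats_noise(self):
        rng = np.random.default_rng(3)
        wf = np.sin(np.linspace(0, np.pi, 251))
        sd = 0.5
        f = np.zeros(260 * 110)
        seeds = np.arange(100) * 260 + 130
        for s in seeds:
            f[s - 125 : s + 126] = wf + rng.normal(0, sd, 251)
        tmpl = estimate_template(f, seeds, 251)
        rms = np.sqrt(np.mean((tmpl - wf) ** 2))
        assert rms < sd / 8

    def test_gross_outlier_excluded(self):
        wf = np.sin(np.linspace(0, np.pi, 251))
        f = np.zeros(260 * 12)
        seeds = np.arange(10) * 260 + 130
        for s in seeds[:-1]:
            f[s - 125 : s + 126] = wf
        f[seeds[-1] - 125 : seeds[-1] + 126] = 40.0 * np.random.default_rng(0).normal(size=251)
        tmpl = estimate_template(f, seeds, 251)
        assert np.sqrt(np.mean((tmpl - wf) ** 2)) < 0.05

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError):
            estimate_template(np.zeros(10_000), np.array([5000, 6000]), 251)


class TestDetection:
    def test_perfect_recovery_at_high_snr(self, spiky_trace):
        trace, truth_times, _, fs = spiky_trace
        params = SpikeDetectParams(fs=fs)
        filtered = preprocess(trace, params)
        idx = (truth_times[:20] * fs).astype(int)
        seeds = np.array([i - 60 + np.argmax(filtered[i - 60 : i + 60]) for i in idx])
        tmpl = estimate_template(filtered, seeds, params.window)
        train = detect_spikes(trace, tmpl, params)
        recall, precision = match_spike_trains(train.times, truth_times, tol_s=1e-3)
        assert recall == 1.0 and precision == 1.0

    def test_pure_noise_yields_no_spikes(self, spiky_trace):
        """Cutoffs established on a spiking cell reject a matched-noise trace."""
        trace, truth_times, _, fs = spiky_trace
        params = SpikeDetectParams(fs=fs)
        filtered = preprocess(trace, params)
        idx = (truth_times[:20] * fs).astype(int)
        seeds = np.array([i - 60 + np.argmax(filtered[i - 60 : i + 60]) for i in idx])
        tmpl = estimate_template(filtered, seeds, params.window)
        ref = detect_spikes(trace, tmpl, params)
        fixed = SpikeDetectParams(fs=fs, shape_cutoff=ref.shape_cutoff, amp_cutoff=ref.amp_cutoff)
        noise = np.random.default_rng(8).normal(0, 1.0, int(10 * fs))
        train = detect_spikes(noise, tmpl, fixed)
        assert len(train) == 0

    def test_offset_invariance_and_amplitude_scaling(self, spiky_trace):
        trace, truth_times, _, fs = spiky_trace
        params = SpikeDetectParams(fs=fs)
        filtered = preprocess(trace, params)
        idx = (truth_times[:20] * fs).astype(int)
        seeds = np.array([i - 60 + np.argmax(filtered[i - 60 : i + 60]) for i in idx])
        tmpl = estimate_template(filtered, seeds, params.window)
        t0 = detect_spikes(trace, tmpl, params)
        t1 = detect_spikes(trace + 100.0, tmpl, params)
        assert np.array_equal(t0.peaks, t1.peaks)
        alpha = 3.0
        t2 = detect_spikes(alpha * trace, alpha * tmpl, params)
        assert np.array_equal(t0.peaks, t2.peaks)
        assert np.allclose(t2.amplitudes, alpha * t0.amplitudes, rtol=1e-9)

    def test_shape_cutoff_monotonicity(self, spiky_trace):
        """Tightening the shape cutoff can only remove detections."""
        trace, truth_times, _, fs = spiky_trace
        params = SpikeDetectParams(fs=fs)
        filtered = preprocess(trace, params)
        idx = (truth_times[:20] * fs).astype(int)
        seeds = np.array([i - 60 + np.argmax(filtered[i - 60 : i + 60]) for i in idx])
        tmpl = estimate_template(filtered, seeds, params.window)
        ref = detect_spikes(trace, tmpl, params)
        prev = np.inf
        for cut in [ref.shape_cutoff * 4, ref.shape_cutoff, ref.shape_cutoff / 4]:
            p = SpikeDetectParams(fs=fs, shape_cutoff=cut, amp_cutoff=ref.amp_cutoff)
            n = len(detect_spikes(trace, tmpl, p))
            assert n <= prev
            prev = n

    def test_inverted_polarity_mode(self, spiky_trace):
        trace, truth_times, _, fs = spiky_trace
        params = SpikeDetectParams(fs=fs, invert=True)
        filtered = preprocess(-trace, SpikeDetectParams(fs=fs))
        idx = (truth_times[:20] * fs).astype(int)
        seeds = np.array([i - 60 + np.argmax(filtered[i - 60 : i + 60]) for i in idx])
        tmpl = estimate_template(filtered, seeds, params.window)
        train = detect_spikes(-trace, tmpl, params)
        recall, precision = match_spike_trains(train.times, truth_times, tol_s=1e-3)
        assert recall == 1.0 and precision == 1.0

    def test_degenerate_template_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(50_000), np.zeros(251), SpikeDetectParams())


class TestOnset:
    def test_logistic_rise_onset_at_max_acceleration(self):
        """For a logistic rise the onset sits at the peak of f''."""
        fs = 50_000.0
        t = np.arange(20_000) / fs
        t0, s = 0.2, 0.001
        trace = 10.0 / (1.0 + np.exp(-(t - t0) / s))
        # the filtered-derivative peak of a sigmoidal rise sits at max slope
        peak = int(t0 * fs)
        # enumeration oracle: argmax of the analytic second derivative
        z = (t - t0) / s
        d2 = np.exp(-z) * (np.exp(-z) - 1.0) / (1.0 + np.exp(-z)) ** 3
        expected = int(np.argmax(d2))
        onset = locate_onset(trace, peak, onset_smooth=5, window=251)
        assert abs(onset - expected) <= 2

    def test_triangle_pulse_onset_at_kink(self):
        trace = np.zeros(10_000)
        kink, peak = 5000, 5050
        trace[kink:peak + 1] = np.linspace(0, 1, peak - kink + 1)
        trace[peak:peak + 51] = np.linspace(1, 0, 51)
        onset = locate_onset(trace, peak, window=251)
        assert abs(onset - kink) <= 3

    def test_bounded_output_on_noise(self):
        rng = np.random.default_rng(5)
        trace = rng.normal(size=10_000)
        peak = 6000
        onset = locate_onset(trace, peak, window=251)
        assert peak - 125 <= onset <= peak

    def test_boundary_peak_rejected(self):
        with pytest.raises(ValueError):
            locate_onset(np.zeros(1000), 2, window=251)
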