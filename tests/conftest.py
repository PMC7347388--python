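"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from flymotor.synthetic import SimConfig, simulate_session


def dtw_reference(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force DTW oracle: full cost matrix, explicit dynamic program.

    Written independently of the package implementation: the squared local
    cost matrix is materialized first, then the cumulative matrix is
    filled row by row.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n, m = a.size, b.size
    cost = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            diff = a[i] - b[j]
            cost[i, j] = diff * diff
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    return float(acc[n, m])


def bh_reference(p_values, q: float) -> np.ndarray:
    """Brute-force Benjamini–Hochberg oracle, straight from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected


@pytest.fixture(scope="session")
def default_session():
    """One default-configuration synthetic session, shared across tests."""
    return simulate_session(SimConfig(seed=11, duration_s=30.0))


@pytest.fixture(scope="session")
def spiky_trace():
    """60 s, 50 kHz trace with 100 inserted spike waveforms at SNR 10.

    Returns (trace, true_peak_times_s, waveform, fs).
    """
    fs = 50_000.0
    dur = 60.0
    rng = np.random.default_rng(7)
    n = int(dur * fs)
    amp, noise_sd = 10.0, 1.0  # SNR = 10
    t_wf = np.arange(int(0.008 * fs)) / fs * 1000.0  # 8 ms
    wf = np.exp(-t_wf / 0.8) - np.exp(-t_wf / 0.33)
    wf = amp * wf / wf.max()
    times = np.sort(rng.uniform(1.0, dur - 1.0, 100))
    # enforce comfortable separation so events do not overlap
    while np.any(np.diff(times) < 0.05):
        times = np.sort(rng.uniform(1.0, dur - 1.0, 100))
    trace = rng.normal(0.0, noise_sd, n)
    peak_offset = int(np.argmax(wf))
    idx = (times * fs).astype(int)
    for i in idx:
        trace[i : i + wf.size] += wf
    peak_times = (idx + peak_offset) / fs
    return trace, peak_times, wf, fs
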