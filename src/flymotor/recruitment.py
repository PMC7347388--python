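"""Spike-triggered force/velocity statistics and force-per-spike curves.

These are the quantities that expose the recruitment hierarchy: the 2-D
histogram of probe force and velocity in the 25 ms following each spike
(fast neurons spike only in high-force, high-velocity regimes, slow
neurons everywhere), the firing rate of a lower-threshold neuron in the
30 ms preceding a higher-threshold neuron's spikes, and the peak force
produced by bursts of n spikes (its slope is the neuron's force-per-spike
gain; the 2-spike/1-spike ratio measures facilitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal


@dataclass
class Hist2D:
    force_edges: NDArray      # µN
    velocity_edges: NDArray   # µN/s or µm/s
    counts: NDArray           # (n_force_bins, n_velocity_bins)
    log_density: NDArray      # log(1 + counts) normalized to max 1
    centroid: tuple[float, float]   # mass-weighted (force, velocity)
    n_frames: int


def probe_velocity(
    positions: ArrayLike, fps: float, sg_window: int = 5, sg_order: int = 2
) -> NDArray:
    """Probe velocity (units/s) from position at the video rate.

    Savitzky–Golay smoothed derivative (window 5, order 2 by default) to
    suppress frame-to-frame tracking jitter.
    """
    x = np.asarray(positions, dtype=float)
    win = sg_window if sg_window % 2 == 1 else sg_window + 1
    return signal.savgol_filter(x, min(win, x.size - (x.size + 1) % 2), min(sg_order, win - 1), deriv=1, delta=1.0 / fps)


def spike_triggered_hist(
    spike_times_s: ArrayLike,
    force: ArrayLike,
    velocity: ArrayLike,
    frame_times_s: ArrayLike,
    window_ms: float = 25.0,
    bins: int | tuple = 30,
    count_once: bool = False,
    force_edges: ArrayLike | None = None,
    velocity_edges: ArrayLike | None = None,
    exclude_mask: ArrayLike | None = None,
) -> Hist2D:
    """2-D histogram of probe force and velocity following each spike.

    Collects all video frames with time in ``(spike, spike + window_ms]``
    for every spike.  By default a frame contributes once per spike window
    containing it (``count_once=True`` collapses duplicates), and the
    mass-weighted centroid is computed from the raw (not log-scaled)
    counts.  ``exclude_mask`` (same length as the frames) removes
    stationary "hotspot" frames before binning.

    Raises on an empty spike train.
    """
    spikes = np.asarray(spike_times_s, dtype=float)
    if spikes.size == 0:
        raise ValueError("empty spike train: cannot build a spike-triggered histogram")
    f = np.asarray(force, dtype=float)
    v = np.asarray(velocity, dtype=float)
    t = np.asarray(frame_times_s, dtype=float)
    w = window_ms / 1000.0

    lo = np.searchsorted(t, spikes, side="right")
    hi = np.searchsorted(t, spikes + w, side="right")
    idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if spikes.size else np.array([], int)
    if count_once:
        idx = np.unique(idx)
    if exclude_mask is not None:
        em = np.asarray(exclude_mask, dtype=bool)
        idx = idx[~em[idx]]
    if idx.size == 0:
        raise ValueError("no frames fall inside any spike window")

    fi, vi = f[idx], v[idx]
    if force_edges is None or velocity_edges is None:
        counts, fe, ve = np.histogram2d(fi, vi, bins=bins)
    else:
        counts, fe, ve = np.histogram2d(fi, vi, bins=[np.asarray(force_edges), np.asarray(velocity_edges)])
    log_density = np.log1p(counts)
    if log_density.max() > 0:
        log_density = log_density / log_density.max()
    centroid = (float(fi.mean()), float(vi.mean()))
    return Hist2D(fe, ve, counts, log_density, centroid, int(idx.size))


def preceding_firing_rate(
    reference_spikes_s: ArrayLike,
    event_spikes_s: ArrayLike,
    window_ms: float = 30.0,
) -> float:
    """Mean firing rate of train A in the window preceding each event of B.

    For each event time ``t`` in B, spikes of A in ``[t − window, t)`` are
    counted; the rate is the mean count divided by the window length.
    A rate above A's session mean indicates that A is already recruited
    when B fires.  Raises on empty B; empty A gives 0 Hz.
    """
    b = np.asarray(event_spikes_s, dtype=float)
    if b.size == 0:
        raise ValueError("no events to trigger on")
    a = np.sort(np.asarray(reference_spikes_s, dtype=float))
    if a.size == 0:
        return 0.0
    w = window_ms / 1000.0
    counts = np.searchsorted(a, b, side="left") - np.searchsorted(a, b - w, side="left")
    return float(counts.mean() / w)


@dataclass
class ForceCurve:
    n_spikes: NDArray         # distinct spike counts, increasing
    peak_force: NDArray       # µN, peak of the per-n average trace
    slope: float | None       # µN/spike from a free-intercept linear fit
    intercept: float | None
    two_to_one_ratio: float | None   # peak(2)/peak(1)


def force_per_spike_curve(
    trials: list[tuple[int, ArrayLike]],
) -> ForceCurve:
    """Peak average force as a function of spikes per burst.

    ``trials`` is a list of ``(n_spikes, baseline-subtracted force trace)``
    pairs; traces within each n are averaged sample-wise (aligned at
    stimulus onset) and the peak taken.  A linear fit (free intercept) of
    peak force against n gives the force-per-spike gain; the 2-spike/
    1-spike peak ratio is reported when both are present.
    """
    if not trials:
        raise ValueError("no trials")
    by_n: dict[int, list[NDArray]] = {}
    for n, trace in trials:
        by_n.setdefault(int(n), []).append(np.asarray(trace, dtype=float))
    ns = np.array(sorted(by_n))
    peaks = np.empty(ns.size)
    for i, n in enumerate(ns):
        group = by_n[n]
        L = min(g.size for g in group)
        peaks[i] = np.mean([g[:L] for g in group], axis=0).max()
    slope = intercept = None
    if ns.size >= 2:
        slope, intercept = (float(c) for c in np.polyfit(ns, peaks, 1))
    ratio = None
    if 1 in by_n and 2 in by_n:
        p1 = peaks[ns == 1][0]
        if p1 != 0:
            ratio = float(peaks[ns == 2][0] / p1)
    return ForceCurve(ns, peaks, slope, intercept, ratio)


def rise_metrics(
    avg_trace: ArrayLike, frame_times_s: ArrayLike
) -> dict[str, float]:
    """Rise kinetics of an average aligned probe trace.

    ``t_half`` is the first time the trace crosses half its peak (linear
    interpolation between frames, in ms from trace start); ``max_velocity``
    is the slope (units/s) of a least-squares line through the rising-phase
    samples between 10% and 90% of the peak.
    """
    y = np.asarray(avg_trace, dtype=float)
    t = np.asarray(frame_times_s, dtype=float)
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        raise ValueError("trace has no positive peak")

    half = peak / 2.0
    above = np.nonzero(y[: peak_idx + 1] >= half)[0]
    i = int(above[0]) if above.size else peak_idx
    if i == 0:
        t_half = t[0]
    else:
        frac = (half - y[i - 1]) / (y[i] - y[i - 1])
        t_half = t[i - 1] + frac * (t[i] - t[i - 1])

    rising = np.arange(peak_idx + 1)
    sel = rising[(y[rising] >= 0.1 * peak) & (y[rising] <= 0.9 * peak)]
    if sel.size >= 2:
        max_velocity = float(np.polyfit(t[sel], y[sel], 1)[0])
    else:  # step-like rise: fall back to the steepest single-frame slope
        dy = np.diff(y[: peak_idx + 1])
        dt = np.diff(t[: peak_idx + 1])
        max_velocity = float((dy / dt).max()) if dy.size else 0.0
    return {"t_half_ms": float((t_half - t[0]) * 1000.0), "max_velocity": max_velocity}
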