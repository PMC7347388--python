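"""Template-based spike detection for whole-cell and EMG traces.

The detector follows a four-step scheme tailored to fly motor neuron
recordings, where somatic spikes can be small and ride on large synaptic
fluctuations:

1. band-pass filter the first derivative of the trace (3-pole Butterworth
   high-pass at 209 Hz cascaded with a 3-pole low-pass at 898 Hz), which
   turns the rapid membrane-potential reversal at the top of each spike
   into a large positive peak;
2. collect candidate events as filtered-trace peaks above a threshold;
3. score each candidate's shape by dynamic time warping (DTW) distance to a
   per-cell template over a 251-sample window;
4. accept candidates with template-like shape AND large raw amplitude.

Spike onsets are localized at the peak of the smoothed second derivative of
the raw trace (the point of maximum acceleration on the rising edge), which
is what conduction-delay measurements need.

Filters are applied causally (no zero-phase filtering) so that latency
structure between soma and EMG events is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal
from scipy.ndimage import uniform_filter1d

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class SpikeDetectParams:
    fs: float = 50_000.0
    hp_cutoff: float = 209.0
    lp_cutoff: float = 898.0
    filter_order: int = 3
    peak_threshold: float | None = None   # filtered-trace units; None → 5× robust sd
    window: int = 251                     # DTW comparison window, samples (odd)
    shape_cutoff: float | None = None     # DTW distance; None → auto clustering
    amp_cutoff: float | None = None       # raw-trace units; None → auto clustering
    onset_smooth: int = 5
    refractory_ms: float = 1.0
    invert: bool = False                  # operate on −trace (EMG polarity)

    def __post_init__(self) -> None:
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.fs / 2):
            raise ValueError("require 0 < hp_cutoff < lp_cutoff < fs/2")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


@dataclass
class SpikeTemplate:
    waveform: NDArray         # filtered-trace template, `window` samples
    window: int
    raw_amplitude: float      # mean raw-trace amplitude of the seed events
    n_events: int

    def __post_init__(self) -> None:
        if self.waveform.size != self.window:
            raise ValueError("template length must equal window")


@dataclass
class SpikeTrain:
    peaks: NDArray            # sample indices of accepted spikes, increasing
    onsets: NDArray           # sample indices, onsets[i] <= peaks[i]
    amplitudes: NDArray       # raw-trace units
    shape_distances: NDArray  # DTW distance to template
    fs: float
    shape_cutoff: float | None = None   # cutoffs actually applied
    amp_cutoff: float | None = None

    @property
    def times(self) -> NDArray:
        """Peak times in seconds."""
        return self.peaks / self.fs

    def __len__(self) -> int:
        return self.peaks.size


def preprocess(trace: ArrayLike, params: SpikeDetectParams) -> NDArray[np.float64]:
    """First derivative of the trace, causally band-passed.

    The derivative is the first difference scaled by the sampling rate
    (units/s); cascaded causal 3-pole Butterworth high- and low-pass
    filters isolate the spike band.  Constant offsets and slow ramps map
    to (asymptotically) zero.
    """
    x = np.asarray(trace, dtype=float)
    if params.invert:
        x = -x
    if x.size <= 10 * params.window:
        raise ValueError("trace too short relative to the template window")
    deriv = np.empty_like(x)
    deriv[1:] = np.diff(x) * params.fs
    deriv[0] = deriv[1]
    bh, ah = signal.butter(params.filter_order, params.hp_cutoff, "highpass", fs=params.fs)
    bl, al = signal.butter(params.filter_order, params.lp_cutoff, "lowpass", fs=params.fs)
    return signal.lfilter(bl, al, signal.lfilter(bh, ah, deriv))


@njit(cache=True)
def _dtw_dp(a: NDArray, b: NDArray) -> float:
    n, m = a.size, b.size
    big = np.inf
    D = np.empty((n + 1, m + 1))
    D[:, 0] = big
    D[0, :] = big
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = a[i - 1] - b[j - 1]
            cost = d * d
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D[n, m]


def dtw_distance(segment_a: ArrayLike, segment_b: ArrayLike) -> float:
    """Classic dynamic-time-warping distance between two equal-length segments.

    Full dynamic program with squared local cost, unit steps
    (match/insert/delete) and no band constraint; symmetric, nonnegative
    and zero iff the segments are identical.  Small local time shifts are
    absorbed by the warping path, which is what makes the distance a good
    shape metric for spike waveforms.
    """
    a = np.ascontiguousarray(segment_a, dtype=np.float64)
    b = np.ascontiguousarray(segment_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("segments must be 1-D")
    if a.size != b.size:
        raise ValueError("segments must have equal length")
    return float(_dtw_dp(a, b))


def _windows(filtered: NDArray, centers: NDArray, window: int) -> tuple[NDArray, NDArray]:
    """Extract `window`-sample segments centered on `centers`; drops edge hits."""
    half = window // 2
    good = (centers >= half) & (centers < filtered.size - half)
    centers = centers[good]
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    return filtered[idx], centers


def estimate_template(
    filtered: ArrayLike,
    seed_peak_indices: ArrayLike,
    window: int = 251,
    drop_quantile: float = 0.90,
) -> NDArray[np.float64]:
    """Average peak-aligned filtered waveforms into a spike template.

    A single refinement pass drops seed events whose DTW distance to the
    initial mean exceeds the ``drop_quantile`` (default 90th percentile)
    and re-averages, which rejects gross outliers among the seeds.
    """
    f = np.asarray(filtered, dtype=float)
    seeds = np.asarray(seed_peak_indices, dtype=int)
    segs, kept = _windows(f, seeds, window)
    if segs.shape[0] < 3:
        raise ValueError("need at least 3 seed events within bounds to build a template")
    mean0 = segs.mean(axis=0)
    dists = np.array([dtw_distance(s, mean0) for s in segs])
    cutoff = np.quantile(dists, drop_quantile)
    keep = dists <= cutoff
    if keep.sum() < 3:
        keep = np.ones(segs.shape[0], dtype=bool)
    return segs[keep].mean(axis=0)


def _candidate_peaks(filtered: NDArray, params: SpikeDetectParams) -> NDArray:
    thr = params.peak_threshold
    if thr is None:
        mad = np.median(np.abs(filtered - np.median(filtered)))
        thr = 5.0 * 1.4826 * mad
    distance = max(int(params.refractory_ms * 1e-3 * params.fs), 1)
    peaks, _ = signal.find_peaks(filtered, height=thr, distance=distance)
    return peaks


def _raw_amplitudes(raw: NDArray, centers: NDArray, window: int, fs: float) -> NDArray:
    """Spike amplitude in the raw trace: local peak minus pre-event baseline.

    The peak is taken within ±1 ms of the candidate (the filtered-derivative
    peak leads the raw spike peak slightly) and the baseline is the median
    of the raw trace 1.25–2.5 ms before it, so the measurement stays local
    to the event rather than picking up neighbors inside the full window.
    """
    near = max(int(1e-3 * fs), 1)
    b0 = max(int(2.5e-3 * fs), 2)
    b1 = max(int(1.25e-3 * fs), 1)
    amps = np.empty(centers.size)
    for i, c in enumerate(centers):
        base = np.median(raw[max(c - b0, 0) : max(c - b1, 1)])
        amps[i] = raw[max(c - near, 0) : c + near + 1].max() - base
    return amps


def _auto_cutoffs(distances: NDArray, amplitudes: NDArray) -> tuple[float, float]:
    """Unsupervised cutoffs: 2-component Gaussian mixture on (log dist, z-amp).

    Candidates are classified by the mixture; the accepted component is
    the one with the better combined score (high amplitude, low
    log-distance).  The cutoffs returned are the extremes of the accepted
    component — its maximum shape distance and minimum amplitude — so the
    thresholding step accepts exactly the candidates the clustering did.
    """
    from sklearn.mixture import GaussianMixture

    if distances.size < 4 or np.ptp(distances) == 0 or np.ptp(amplitudes) == 0:
        return float(np.max(distances)), float(np.min(amplitudes))
    logd = np.log(distances + 1e-12)
    za = (amplitudes - amplitudes.mean()) / amplitudes.std()
    zd = (logd - logd.mean()) / max(logd.std(), 1e-12)
    X = np.column_stack([zd, za])
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(X)
    labels = gm.predict(X)
    score = gm.means_[:, 1] - gm.means_[:, 0]  # high amp, low log-dist wins
    good = int(np.argmax(score))
    sel = labels == good
    if not sel.any():
        sel = np.ones(distances.size, dtype=bool)
    return float(distances[sel].max()), float(amplitudes[sel].min())


def detect_spikes(
    trace: ArrayLike,
    template: NDArray | SpikeTemplate,
    params: SpikeDetectParams,
) -> SpikeTrain:
    """Run the full 4-step detector on a raw trace.

    Candidates are local maxima of the band-passed derivative above
    ``peak_threshold`` separated by at least the refractory interval; each
    is scored with (DTW distance to the template, raw amplitude) and
    accepted iff ``distance <= shape_cutoff`` and
    ``amplitude >= amp_cutoff``.  Cutoffs left as ``None`` are set by
    unsupervised 2-component clustering of the candidate scores.
    """
    raw = np.asarray(trace, dtype=float)
    tmpl = template.waveform if isinstance(template, SpikeTemplate) else np.asarray(template, float)
    if tmpl.size != params.window:
        raise ValueError("template length must equal params.window")
    if not np.any(tmpl):
        raise ValueError("degenerate template (all zeros)")

    filtered = preprocess(raw, params)
    work = -raw if params.invert else raw
    centers = _candidate_peaks(filtered, params)
    segs, centers = _windows(filtered, centers, params.window)
    if centers.size == 0:
        empty = np.array([], dtype=int)
        return SpikeTrain(empty, empty, np.array([]), np.array([]), params.fs)

    dists = np.array([dtw_distance(s, tmpl) for s in segs])
    amps = _raw_amplitudes(work, centers, params.window, params.fs)

    shape_cut, amp_cut = params.shape_cutoff, params.amp_cutoff
    if shape_cut is None or amp_cut is None:
        auto_shape, auto_amp = _auto_cutoffs(dists, amps)
        shape_cut = auto_shape if shape_cut is None else shape_cut
        amp_cut = auto_amp if amp_cut is None else amp_cut

    accept = (dists <= shape_cut) & (amps >= amp_cut)
    peaks = centers[accept]
    onsets = np.array(
        [locate_onset(work, int(p), params.onset_smooth, params.window) for p in peaks],
        dtype=int,
    )
    return SpikeTrain(
        peaks, onsets, amps[accept], dists[accept], params.fs,
        shape_cutoff=float(shape_cut), amp_cutoff=float(amp_cut),
    )


def detect_spikes_auto(
    trace: ArrayLike, params: SpikeDetectParams, n_seeds: int = 20
) -> tuple[SpikeTrain, SpikeTemplate]:
    """Detect spikes with a self-seeded template.

    The template is estimated from the top-``n_seeds`` candidates by
    filtered peak height, then the standard detector runs.
    """
    raw = np.asarray(trace, dtype=float)
    filtered = preprocess(raw, params)
    centers = _candidate_peaks(filtered, params)
    if centers.size < 3:
        raise ValueError("too few candidate events to seed a template")
    order = np.argsort(filtered[centers])[::-1]
    seeds = np.sort(centers[order[:n_seeds]])
    tmpl_wave = estimate_template(filtered, seeds, params.window)
    work = -raw if params.invert else raw
    seg_seeds, kept = _windows(filtered, seeds, params.window)
    raw_amp = float(np.mean(_raw_amplitudes(work, kept, params.window, params.fs)))
    template = SpikeTemplate(tmpl_wave, params.window, raw_amp, kept.size)
    return detect_spikes(trace, template, params), template


def locate_onset(
    raw_trace: ArrayLike, peak_index: int, onset_smooth: int = 5, window: int = 251
) -> int:
    """Spike onset: peak of the smoothed second derivative before the peak.

    The second difference of the raw trace is boxcar-smoothed over
    ``onset_smooth`` samples; the onset is its argmax within the
    half-window preceding ``peak_index`` — the point of maximum
    acceleration at the foot of the spike.  Always returns an index in
    ``[peak_index - window//2, peak_index]``.
    """
    x = np.asarray(raw_trace, dtype=float)
    half = window // 2
    if peak_index <= half // 2 or peak_index >= x.size:
        raise ValueError("peak too close to the trace boundary to localize an onset")
    lo = max(peak_index - half, 1)
    seg = x[lo - 1 : peak_index + 1]
    d2 = np.diff(seg, n=2)
    if d2.size == 0:
        return peak_index
    d2s = uniform_filter1d(d2, size=max(onset_smooth, 1))
    return lo + int(np.argmax(d2s))


def match_spike_trains(
    detected_s: ArrayLike, truth_s: ArrayLike, tol_s: float = 1e-3
) -> tuple[float, float]:
    """(recall, precision) of detected spike times against ground truth.

    Greedy one-to-one matching within ``tol_s`` (default ±1 ms).
    """
    det = np.sort(np.asarray(detected_s, dtype=float))
    tru = np.sort(np.asarray(truth_s, dtype=float))
    used = np.zeros(det.size, dtype=bool)
    hits = 0
    for t in tru:
        i = np.searchsorted(det, t)
        best, best_d = -1, tol_s
        for j in (i - 1, i):
            if 0 <= j < det.size and not used[j] and abs(det[j] - t) <= best_d:
                best, best_d = j, abs(det[j] - t)
        if best >= 0:
            used[best] = True
            hits += 1
    recall = hits / tru.size if tru.size else 1.0
    precision = hits / det.size if det.size else 1.0
    return recall, precision
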