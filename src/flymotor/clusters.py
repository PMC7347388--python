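"""Segmentation of femur muscle movies into motor-unit activity clusters.

Pixels whose fluorescence co-varies belong to muscle fibers driven by the
same motor unit.  The pipeline: k-means over pixel time series with a
correlation distance; spatial refinement that keeps only pixels whose
smoothed neighborhood supports their label (threshold 0.75); per-cluster
ΔF/F traces with an occlusion rule (a frame is dropped for a cluster when
a moving occluder — e.g. the force probe — covers >40% of its pixels); and
activation detection by thresholding the Savitzky–Golay derivative of the
calcium trace at twice the noise s.d. estimated from negative derivatives
(the indicator decays slowly, so negative derivatives are noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal
from scipy.ndimage import gaussian_filter

from .synthetic import PixelMovie


@dataclass
class ClusterMap:
    labels: NDArray       # (H, W) int, 0 = background/excluded, 1..K clusters
    n_clusters: int
    roi: NDArray          # (H, W) bool
    pixel_counts: NDArray  # per-cluster retained pixel counts, length K

    def member_mask(self, k: int) -> NDArray:
        return self.labels == k


@dataclass
class ClusterTraces:
    dff: NDArray              # (T, K) ΔF/F, nan where invalid
    raw: NDArray              # (T, K) mean fluorescence of visible pixels
    valid: NDArray            # (T, K) bool
    occlusion_fraction: NDArray  # (T, K)
    times: NDArray            # s
    fps: float


def cluster_pixels(
    movie: PixelMovie | NDArray,
    roi: ArrayLike,
    n_clusters: int = 6,
    seed: int = 0,
    n_init: int = 5,
    fps: float | None = None,
) -> ClusterMap:
    """K-means segmentation of pixel time series with a correlation metric.

    Each ROI pixel's time series is z-scored so that Euclidean k-means acts
    on ``1 − Pearson r`` (for unit-variance series, ``||a − b||² =
    2T(1 − r)``).  Zero-variance pixels are excluded before clustering.
    The best of ``n_init`` seeded restarts (by inertia) is kept, and
    cluster labels are renumbered ventral→dorsal by the row coordinate of
    each cluster's centroid so numbering is anatomically stable.
    """
    from sklearn.cluster import KMeans

    frames = movie.frames if isinstance(movie, PixelMovie) else np.asarray(movie, float)
    if frames.ndim != 3:
        raise ValueError("movie must be (T, H, W)")
    if frames.shape[0] < 50:
        raise ValueError("need at least 50 frames to cluster pixel dynamics")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != frames.shape[1:]:
        raise ValueError("roi shape must match frame shape")
    if not roi.any():
        raise ValueError("roi is empty")

    X = frames[:, roi].T  # (n_pixels, T)
    sd = X.std(axis=1)
    active = sd > 0
    labels_img = np.zeros(roi.shape, dtype=int)
    if not active.any():
        warnings.warn("all ROI pixels have zero variance; returning empty cluster map")
        return ClusterMap(labels_img, n_clusters, roi, np.zeros(n_clusters, dtype=int))
    if n_clusters > active.sum():
        raise ValueError("n_clusters exceeds the number of usable pixels")

    Z = (X[active] - X[active].mean(axis=1, keepdims=True)) / sd[active, None]
    if n_clusters == 1:
        assign = np.zeros(Z.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
        assign = km.fit_predict(Z)

    rr, cc = np.nonzero(roi)
    rr_a, cc_a = rr[active], cc[active]
    # ventral→dorsal renumbering by centroid row
    order = np.argsort([rr_a[assign == k].mean() for k in range(n_clusters)])
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(1, n_clusters + 1)
    labels_img[rr_a, cc_a] = remap[assign]
    counts = np.array([(labels_img == k).sum() for k in range(1, n_clusters + 1)])
    return ClusterMap(labels_img, n_clusters, roi, counts)


def refine_cluster_map(
    raw_map: ClusterMap, sigma_px: float = 2.0, support: float = 0.75
) -> ClusterMap:
    """Drop pixels without sufficient same-label neighborhood support.

    Each cluster's binary indicator image is Gaussian-smoothed
    (sigma ``sigma_px``); pixels whose smoothed support falls below
    ``support`` (default 0.75, i.e. less than ~3/4 of the local
    neighborhood shares their label) are excluded (label 0).  Solid
    cluster interiors are untouched; isolated pixels and fine interdigitation
    are removed.
    """
    labels = raw_map.labels
    out = np.zeros_like(labels)
    for k in range(1, raw_map.n_clusters + 1):
        ind = (labels == k).astype(float)
        sm = gaussian_filter(ind, sigma=sigma_px, mode="constant")
        out[(labels == k) & (sm >= support)] = k
    counts = np.array([(out == k).sum() for k in range(1, raw_map.n_clusters + 1)])
    return ClusterMap(out, raw_map.n_clusters, raw_map.roi, counts)


def extract_cluster_traces(
    movie: PixelMovie | NDArray,
    cluster_map: ClusterMap,
    occluder: ArrayLike | None = None,
    fps: float | None = None,
    occlusion_limit: float = 0.40,
    f0_percentile: float = 10.0,
) -> ClusterTraces:
    """Per-cluster ΔF/F with the >40% occlusion exclusion rule.

    Per frame, a cluster's fluorescence is the mean of its *visible* member
    pixels.  Frames where the occluder covers more than
    ``occlusion_limit`` of a cluster's pixels are marked invalid for that
    cluster.  ΔF/F = (F − F0)/F0 with F0 the ``f0_percentile``-th
    percentile (default 10th) of the cluster's valid trace — a baseline
    robust to activity-dominated recordings.
    """
    if isinstance(movie, PixelMovie):
        frames, times, fps = movie.frames, movie.times, movie.fps
    else:
        frames = np.asarray(movie, float)
        if fps is None:
            raise ValueError("fps required when movie is a bare array")
        times = np.arange(frames.shape[0]) / fps
    K = cluster_map.n_clusters
    if not (cluster_map.labels > 0).any():
        raise ValueError("cluster map is empty")
    T = frames.shape[0]
    occ = None if occluder is None else np.asarray(occluder, dtype=bool)

    raw = np.full((T, K), np.nan)
    occ_frac = np.zeros((T, K))
    for j, k in enumerate(range(1, K + 1)):
        member = cluster_map.member_mask(k)
        n_member = int(member.sum())
        if n_member == 0:
            continue
        pix = frames[:, member]  # (T, n_member)
        if occ is None:
            raw[:, j] = pix.mean(axis=1)
        else:
            covered = occ[:, member]
            occ_frac[:, j] = covered.mean(axis=1)
            visible = ~covered
            n_vis = visible.sum(axis=1)
            with np.errstate(invalid="ignore"):
                raw[:, j] = np.where(
                    n_vis > 0, np.where(visible, pix, 0.0).sum(axis=1) / np.maximum(n_vis, 1), np.nan
                )
    valid = occ_frac <= occlusion_limit
    valid &= np.isfinite(raw)

    dff = np.full_like(raw, np.nan)
    for j in range(K):
        v = valid[:, j]
        if not v.any():
            warnings.warn(f"cluster {j + 1} has no valid frames")
            continue
        f0 = np.percentile(raw[v, j], f0_percentile)
        if f0 == 0:
            f0 = np.finfo(float).eps
        dff[v, j] = (raw[v, j] - f0) / f0
    return ClusterTraces(dff, raw, valid, occ_frac, times, float(fps))


def detect_activations(
    traces: ClusterTraces,
    video_times: ArrayLike,
    polyorder: int = 7,
    window_length: int = 9,
    threshold_mult: float = 2.0,
) -> list[list[tuple[float, float]]]:
    """Cluster activation intervals from the calcium-trace derivative.

    The ΔF/F trace (calcium frame rate) is Savitzky–Golay filtered with a
    simultaneous derivative (default polynomial order 7, frame length 9)
    and both are interpolated onto the faster video time grid.  Because
    the indicator's decay is slow relative to leg movements, negative
    derivative samples reflect noise; their s.d. (computed by mirroring
    the negative lobe) scaled by ``threshold_mult`` (default 2) thresholds
    the positive derivatives.  Returns one list of ``(start_s, end_s)``
    intervals per cluster.
    """
    vt = np.asarray(video_times, dtype=float)
    wl = window_length if window_length % 2 == 1 else window_length + 1
    po = min(polyorder, wl - 1)
    dt_ca = 1.0 / traces.fps
    out: list[list[tuple[float, float]]] = []
    for j in range(traces.dff.shape[1]):
        v = traces.valid[:, j]
        if v.sum() < wl:
            out.append([])
            continue
        t_ca = traces.times[v]
        y = traces.dff[v, j]
        smooth = signal.savgol_filter(y, wl, po)
        deriv = signal.savgol_filter(y, wl, po, deriv=1, delta=dt_ca)
        d_vid = np.interp(vt, t_ca, deriv)
        neg = d_vid[d_vid < 0]
        sd = np.sqrt(np.mean(neg**2)) if neg.size else 0.0
        thr = threshold_mult * sd
        if thr == 0:
            thr = np.finfo(float).eps
        active = d_vid > thr
        out.append(_runs_to_intervals(active, vt))
    return out


def _runs_to_intervals(active: NDArray, times: NDArray) -> list[tuple[float, float]]:
    edges = np.diff(active.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if active.size and active[0]:
        starts.insert(0, 0)
    if active.size and active[-1]:
        stops.append(active.size - 1)
    return [(float(times[s]), float(times[min(e, active.size - 1)])) for s, e in zip(starts, stops)]


def activation_mask(
    intervals: list[tuple[float, float]], times: ArrayLike
) -> NDArray[np.bool_]:
    """Boolean per-frame activity mask from a list of (start, end) intervals."""
    t = np.asarray(times, dtype=float)
    mask = np.zeros(t.size, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t <= e)
    return mask


def posture_contrast(
    traces: ClusterTraces,
    joint_angles: ArrayLike,
    extended_deg: float = 120.0,
    flexed_deg: float = 30.0,
) -> list[dict]:
    """Mean ΔF/F of each cluster with the leg extended vs flexed.

    Extended frames have femur–tibia angle > ``extended_deg`` (default
    120°), flexed < ``flexed_deg`` (default 30°); intermediate postures
    are ignored.  Returns per-cluster dicts with the two group means and
    frame counts; significance testing is left to stock routines.
    """
    angles = np.asarray(joint_angles, dtype=float)
    if angles.size != traces.dff.shape[0]:
        raise ValueError("joint_angles must have one entry per movie frame")
    ext = angles > extended_deg
    flx = angles < flexed_deg
    out = []
    for j in range(traces.dff.shape[1]):
        v = traces.valid[:, j]
        for name, mask in (("extended", ext & v), ("flexed", flx & v)):
            if not mask.any():
                raise ValueError(f"no {name} frames for cluster {j + 1}")
        out.append(
            dict(
                cluster=j + 1,
                mean_dff_extended=float(np.nanmean(traces.dff[ext & v, j])),
                mean_dff_flexed=float(np.nanmean(traces.dff[flx & v, j])),
                n_extended=int((ext & v).sum()),
                n_flexed=int((flx & v).sum()),
            )
        )
    return out
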