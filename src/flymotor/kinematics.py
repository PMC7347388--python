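"""True femur–tibia joint angles from tracked leg points.

A camera views the leg's swing plane at an oblique (azimuthal) angle, so
the circular arc swept by the tibia projects to an ellipse whose
minor/major axis ratio is cos(azimuth).  The pipeline: clean the six
tracked tibia points per frame (nearest-neighbor outlier detection, single
misidentified points filled, multi-point frames excluded, median filter),
fit a direct least-squares ellipse to the tibia centroids, recover the
azimuth as arccos(b/a), unproject each centroid back onto the circular
arc, and measure the true joint angle relative to the femur axis
(180° = straight leg; extended > 120°, flexed < 30°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.ndimage import median_filter
from skimage.measure import EllipseModel

from .synthetic import TrackedPoints


@dataclass
class CleanedPoints:
    femur: NDArray        # (T, 6, 2), median-filtered
    tibia: NDArray        # (T, 6, 2), filled + median-filtered
    centroid: NDArray     # (T, 2) tibia centroid
    valid: NDArray        # (T,) bool, False where frame excluded
    reasons: dict[int, str] = field(default_factory=dict)   # frame -> exclusion reason
    fills: list[tuple[int, int]] = field(default_factory=list)  # (frame, point) filled


@dataclass
class LegArcModel:
    center: tuple[float, float]
    a: float                  # semi-major, px
    b: float                  # semi-minor, px (b <= a)
    orientation: float        # radians, major-axis direction
    azimuth_deg: float        # arccos(b/a)
    femur_axis: tuple[float, float]  # unit vector, femur base -> joint

    @property
    def axis_ratio(self) -> float:
        return self.b / self.a


def _nn_distances(points: NDArray) -> NDArray:
    """Per-point nearest-neighbor distance within each frame. points: (T, P, 2)."""
    diff = points[:, :, None, :] - points[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    P = points.shape[1]
    d[:, np.arange(P), np.arange(P)] = np.inf
    return d.min(axis=2)  # (T, P)


def clean_points(
    points: TrackedPoints,
    outlier_sd: float = 5.0,
    median_width: int = 5,
    seed: int = 0,
) -> CleanedPoints:
    """Outlier repair and temporal smoothing of tracked tibia points.

    The pooled distribution of per-frame nearest-neighbor distances among
    the six tibia points sets a robust outlier threshold
    (median + ``outlier_sd`` × 1.4826·MAD).  Frames with exactly one
    outlying point get that point re-drawn: target distances to the other
    five points are sampled from their per-pair empirical distance
    distributions and the point is placed by least squares against them.
    Frames with two or more outlying points are excluded (reason
    "multi-point").  Coordinates are then median-filtered over
    ``median_width`` frames and the tibia centroid appended.
    """
    from scipy.optimize import least_squares

    tibia = np.array(points.tibia, dtype=float)
    femur = np.array(points.femur, dtype=float)
    T, P, _ = tibia.shape
    if T < 100:
        raise ValueError("need at least 100 frames to estimate distance distributions")
    rng = np.random.default_rng(seed)

    nn = _nn_distances(tibia)
    med = np.median(nn)
    mad = np.median(np.abs(nn - med))
    thr = med + outlier_sd * 1.4826 * mad
    outlier = nn > thr   # (T, P)
    n_out = outlier.sum(axis=1)

    valid = np.ones(T, dtype=bool)
    reasons: dict[int, str] = {}
    fills: list[tuple[int, int]] = []

    # pooled per-pair distance samples from clean frames only
    clean_frames = n_out == 0
    pair_d = np.sqrt(
        ((tibia[clean_frames, :, None, :] - tibia[clean_frames, None, :, :]) ** 2).sum(-1)
    )  # (Tc, P, P)

    for fr in np.nonzero(n_out >= 2)[0]:
        valid[fr] = False
        reasons[int(fr)] = "multi-point"

    for fr in np.nonzero(n_out == 1)[0]:
        j = int(np.nonzero(outlier[fr])[0][0])
        others = [i for i in range(P) if i != j]
        targets = np.array(
            [pair_d[rng.integers(pair_d.shape[0]), j, i] for i in others]
        )
        anchors = tibia[fr, others]

        def resid(p):
            return np.sqrt(((anchors - p) ** 2).sum(axis=1)) - targets

        p0 = anchors.mean(axis=0)
        sol = least_squares(resid, p0)
        tibia[fr, j] = sol.x
        fills.append((int(fr), j))

    w = max(int(median_width), 1)
    tibia_f = median_filter(tibia, size=(w, 1, 1), mode="nearest")
    femur_f = median_filter(femur, size=(w, 1, 1), mode="nearest")
    centroid = tibia_f.mean(axis=1)
    return CleanedPoints(femur_f, tibia_f, centroid, valid, reasons, fills)


def fit_arc(
    centroids: ArrayLike,
    femur_points: ArrayLike | None = None,
    min_frames: int = 20,
    min_span_deg: float = 60.0,
) -> LegArcModel:
    """Direct least-squares ellipse fit to tibia centroids.

    The azimuthal tilt of the leg's swing plane is ``arccos(b/a)`` of the
    fitted ellipse.  Raises for degenerate (collinear) inputs or if the
    centroids span less than ``min_span_deg`` of arc around the fitted
    center.  If ``femur_points`` (any array of points on the femur axis)
    are given, the stored femur-axis direction points from their mean
    toward the ellipse center; otherwise it defaults to +x.
    """
    pts = np.asarray(centroids, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < min_frames:
        raise ValueError(f"need at least {min_frames} centroid frames")
    # collinearity check via PCA
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] < 1e-9 * max(evals[1], 1e-12):
        raise ValueError("degenerate (collinear) centroids; cannot fit an ellipse")

    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    span = _angular_span(pts, (xc, yc))
    if span < min_span_deg:
        raise ValueError(f"centroids span only {span:.1f} deg of arc (< {min_span_deg})")
    azimuth = float(np.degrees(np.arccos(np.clip(b / a, 0.0, 1.0))))

    if femur_points is not None:
        fp = np.asarray(femur_points, dtype=float).reshape(-1, 2)
        v = np.array([xc, yc]) - fp.mean(axis=0)
        femur_axis = tuple(v / np.linalg.norm(v))
    else:
        femur_axis = (1.0, 0.0)
    return LegArcModel((float(xc), float(yc)), float(a), float(b), float(theta % np.pi), azimuth, femur_axis)


def _angular_span(pts: NDArray, center: tuple[float, float]) -> float:
    ang = np.sort(np.degrees(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0])))
    gaps = np.diff(np.r_[ang, ang[0] + 360.0])
    return 360.0 - gaps.max()


def unproject(points: ArrayLike, arc: LegArcModel) -> NDArray:
    """Map points from the image plane back into the leg's swing plane.

    Coordinates are rotated into the ellipse frame, the minor-axis
    component is divided by cos(azimuth) (= b/a), and the result is
    returned in the original frame — the fitted ellipse maps to the circle
    of radius ``a``.  At azimuth 0 this is the identity.
    """
    p = np.asarray(points, dtype=float) - np.asarray(arc.center)
    ct, st = np.cos(arc.orientation), np.sin(arc.orientation)
    R = np.array([[ct, st], [-st, ct]])
    q = p @ R.T
    q[..., 1] /= max(arc.axis_ratio, 1e-12)
    return q @ R + np.asarray(arc.center)


def joint_angles(
    cleaned: CleanedPoints,
    arc: LegArcModel,
    extended_deg: float = 120.0,
    flexed_deg: float = 30.0,
    residual_sd_limit: float = 3.0,
) -> tuple[NDArray, list[str], NDArray]:
    """True femur–tibia joint angle per frame, with posture labels.

    Each tibia centroid is unprojected onto the circular arc; the joint
    angle is 180° minus the angle between the femur axis (also
    unprojected) and the joint→centroid direction, so a straight leg reads
    180°.  Frames whose unprojected centroid lies far off the circle
    (radial residual > ``residual_sd_limit`` robust s.d.) are flagged
    invalid.  Labels: "extended" (> 120°), "flexed" (< 30°), "mid";
    excluded/flagged frames are labeled "invalid".

    Returns ``(angles_deg, labels, valid)``.
    """
    center = np.asarray(arc.center)
    up = unproject(cleaned.centroid, arc)
    rel = up - center

    # femur axis direction in the unprojected (swing) plane
    fbase = cleaned.femur.mean(axis=(0, 1))
    fdir = unproject(np.array([fbase]), arc)[0] - center
    norm = np.linalg.norm(fdir)
    fhat = -fdir / norm if norm > 0 else np.array([-1.0, 0.0])
    # fdir points center->femur; the distal femur direction is the opposite

    r = np.linalg.norm(rel, axis=1)
    resid = r - arc.a
    sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    off_arc = np.abs(resid - np.median(resid)) > residual_sd_limit * max(sd, 1e-12)

    with np.errstate(invalid="ignore"):
        cosphi = np.clip((rel @ fhat) / np.maximum(r, 1e-12), -1.0, 1.0)
    phi = np.degrees(np.arccos(cosphi))
    angles = 180.0 - phi

    valid = cleaned.valid & ~off_arc
    labels = [
        "invalid" if not v else ("extended" if a > extended_deg else "flexed" if a < flexed_deg else "mid")
        for a, v in zip(angles, valid)
    ]
    angles = np.where(valid, angles, np.nan)
    return angles, labels, valid
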