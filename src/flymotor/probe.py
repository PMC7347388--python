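"""Force-probe physics: tracking, calibration, ring-down fitting, force reconstruction.

The force probe is a flexible fiber the fly pulls on with its tibia.  At
steady state it behaves as a linear spring, ``F = k x``, but because it has
effective mass *m* and sits in saline with drag *c* its full dynamics are a
damped harmonic oscillator::

    F(t) = m x'' + c x' + k x

Units are chosen so the three terms are commensurate: displacement in µm,
time in ms, force in µN, mass in mg and drag in mg/ms (1 mg/ms = 1 kg/s
per 1e4; note 1 µN = 1 mg·µm/ms²).  With the calibrated parameters
(k = 0.2234 µN/µm, m = 0.1702 mg, c = 0.1377 mg/ms) the probe is slightly
underdamped, with relaxation time constant tau = 2m/c ≈ 2.47 ms and damped
oscillation period ≈ 5.86 ms — fast enough that at a 170 Hz video rate the
probe effectively tracks the applied force quasistatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal


@dataclass(frozen=True)
class ProbeModel:
    """Second-order model of the force probe.

    Parameters
    ----------
    k : float
        Spring constant, µN/µm.
    m : float
        Effective mass, mg.
    c : float
        Drag coefficient, mg/ms (equivalently kg/s × 1e4).
    """

    k: float = 0.2234
    m: float = 0.1702
    c: float = 0.1377

    def __post_init__(self) -> None:
        if self.k <= 0 or self.m <= 0 or self.c <= 0:
            raise ValueError("probe parameters k, m, c must be positive")

    @property
    def tau(self) -> float:
        """Exponential decay time constant of the free response, ms (= 2m/c)."""
        return 2.0 * self.m / self.c

    @property
    def omega0_sq(self) -> float:
        """Squared undamped angular frequency, rad²/ms² (= k/m)."""
        return self.k / self.m

    @property
    def is_underdamped(self) -> bool:
        return self.omega0_sq > (self.c / (2.0 * self.m)) ** 2

    @property
    def omega_d(self) -> float:
        """Damped angular frequency, rad/ms.  Raises if overdamped."""
        disc = self.omega0_sq - (self.c / (2.0 * self.m)) ** 2
        if disc <= 0:
            raise ValueError("probe is not underdamped; no oscillation frequency")
        return float(np.sqrt(disc))

    @property
    def period(self) -> float:
        """Damped oscillation period, ms (= 2π/ω_d)."""
        return 2.0 * np.pi / self.omega_d


def track_probe_position(
    frame: ArrayLike,
    axis_line: tuple[tuple[float, float], tuple[float, float]],
    pixel_size: float = 1.0,
) -> tuple[float, float]:
    """Locate the probe in one video frame as a position along its travel axis.

    The image is rotated (bilinear interpolation) so that ``axis_line`` —
    two ``(row, col)`` endpoints spanning the probe's travel — is horizontal,
    rows are averaged into a single intensity profile, and the probe position
    is the center of mass of profile samples within ±FWHM of the brightest
    peak, measured above the profile median (baseline).

    Returns
    -------
    (position, quality)
        Position in µm along the axis from the first endpoint, and the peak
        prominence above baseline in intensity units.  A frame with no peak
        above baseline (e.g. uniform image) returns ``(nan, 0.0)`` rather
        than raising.
    """
    img = np.asarray(frame, dtype=float)
    (r0, c0), (r1, c1) = axis_line
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise ValueError("axis_line endpoints must lie within the image")

    length = float(np.hypot(r1 - r0, c1 - c0))
    n = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    # Sample a band of profiles parallel to the axis (±3 px) and average.
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    nr, nc = -uc, ur  # unit normal
    offsets = np.arange(-3, 4)
    rows = r0 + t[None, :] * (r1 - r0) + offsets[:, None] * nr
    cols = c0 + t[None, :] * (c1 - c0) + offsets[:, None] * nc
    profile = _bilinear(img, rows, cols).mean(axis=0)

    baseline = float(np.median(profile))
    peak_idx = int(np.argmax(profile))
    prominence = profile[peak_idx] - baseline
    if prominence <= 1e-12 or np.ptp(profile) < 1e-12:
        return float("nan"), 0.0

    half = baseline + prominence / 2.0
    above = profile >= half
    # contiguous run containing the peak = samples within FWHM
    left = peak_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak_idx
    while right < n - 1 and above[right + 1]:
        right += 1
    seg = slice(left, right + 1)
    # weight relative to the half-max level: edge samples get ~zero weight,
    # which removes the truncation bias of a hard FWHM window
    weights = profile[seg] - half
    pos_px = float(np.sum(np.arange(left, right + 1) * weights) / np.sum(weights))
    scale = length / (n - 1)  # px per sample along the axis
    return pos_px * scale * pixel_size, float(prominence)


def _bilinear(img: NDArray, rows: NDArray, cols: NDArray) -> NDArray:
    """Bilinear image sampling with edge clamping."""
    r = np.clip(rows, 0, img.shape[0] - 1)
    c = np.clip(cols, 0, img.shape[1] - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, img.shape[0] - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, img.shape[1] - 2)
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0 + 1, c0] * fr * (1 - fc)
        + img[r0, c0 + 1] * (1 - fr) * fc
        + img[r0 + 1, c0 + 1] * fr * fc
    )


@dataclass(frozen=True)
class CalibrationFit:
    k: float            # slope, µN/µm
    intercept: float    # µN
    k_stderr: float     # standard error of the slope
    residual_sd: float  # residual standard deviation, µN


def calibrate_spring_constant(positions: ArrayLike, forces: ArrayLike) -> CalibrationFit:
    """Fit the spring constant as the OLS slope of force against position.

    Mirrors the balance calibration: the probe is deflected to a series of
    positions and the reaction force recorded; the spring constant is the
    slope of the force–position line.

    Raises
    ------
    ValueError
        Fewer than 3 distinct positions, or all positions identical
        (degenerate design).
    """
    x = np.asarray(positions, dtype=float)
    f = np.asarray(forces, dtype=float)
    if x.shape != f.shape or x.ndim != 1:
        raise ValueError("positions and forces must be 1-D arrays of equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct probe positions to calibrate")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all positions identical")

    X = np.column_stack([x, np.ones_like(x)])
    coef, res, _, _ = np.linalg.lstsq(X, f, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = f - X @ coef
    dof = max(x.size - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    return CalibrationFit(slope, intercept, float(np.sqrt(s2 / sxx)), float(np.sqrt(s2)))


@dataclass(frozen=True)
class RingdownFit:
    m: float        # mg
    c: float        # mg/ms
    tau: float      # ms
    period: float   # ms (nan if overdamped)
    overdamped: bool
    amplitude: float
    phase: float
    baseline: float


def fit_flick_dynamics(ringdown: ArrayLike, k: float, fs: float) -> RingdownFit:
    """Extract probe mass and drag from a free ring-down ("flick") trace.

    The probe is deflected and abruptly released; its free relaxation is
    imaged at >= 1 kHz.  The underdamped free response

        x(t) = A exp(-t/tau) cos(omega_d t + phi) + baseline

    is fitted by nonlinear least squares; mass and drag follow from
    ``m = k/(omega_d^2 + 1/tau^2)`` and ``c = 2 m / tau``.

    If the trace never crosses its resting baseline after release (no
    oscillation), an overdamped biexponential ``A1 e^(-t/t1) + A2 e^(-t/t2)``
    is fitted instead and the result flagged ``overdamped=True``; m and c are
    then derived from the two real decay rates of the overdamped oscillator.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(ringdown, dtype=float)
    if fs < 1000:
        raise ValueError("ring-down must be sampled at >= 1 kHz to resolve ~2.5 ms dynamics")
    if x.size < 10:
        raise ValueError("ring-down trace too short")
    dt = 1000.0 / fs  # ms per sample
    t = np.arange(x.size) * dt
    baseline0 = float(np.median(x[-max(x.size // 10, 5):]))
    centered = x - baseline0

    # Oscillation check: does the trace cross baseline after release?
    crossings = np.nonzero(np.diff(np.signbit(centered)))[0]
    oscillates = crossings.size >= 1 and np.max(np.abs(centered[crossings[0] + 1:])) > 0.02 * np.max(
        np.abs(centered)
    )

    if oscillates:
        # frequency seed from the dominant FFT component
        spec = np.abs(np.fft.rfft(centered * np.hanning(centered.size)))
        freqs = np.fft.rfftfreq(centered.size, d=dt)  # cycles/ms
        wd0 = 2 * np.pi * max(freqs[np.argmax(spec[1:]) + 1], 1.0 / t[-1])
        tau0 = max(t[-1] / 4.0, dt)

        def damped(tt, A, tau, wd, phi, b):
            return A * np.exp(-tt / tau) * np.cos(wd * tt + phi) + b

        p0 = [centered[0], tau0, wd0, 0.0, baseline0]
        popt, _ = curve_fit(damped, t, x, p0=p0, maxfev=20000)
        A, tau, wd, phi, b = popt
        tau, wd = abs(float(tau)), abs(float(wd))
        m = k / (wd**2 + 1.0 / tau**2)
        c = 2.0 * m / tau
        return RingdownFit(m, c, tau, 2 * np.pi / wd, False, float(A), float(phi), float(b))

    # Overdamped: x(t) = A1 exp(-r1 t) + A2 exp(-r2 t) with r1, r2 the real
    # roots of m r^2 - c r + k = 0 → m = k/(r1 r2), c = m (r1 + r2).
    def biexp(tt, A1, r1, A2, r2, b):
        return A1 * np.exp(-r1 * tt) + A2 * np.exp(-r2 * tt) + b

    r0 = 1.0 / max(t[-1] / 4.0, dt)
    p0 = [centered[0], r0 * 2, -centered[0] * 0.1, r0 / 2, baseline0]
    try:
        popt, _ = curve_fit(biexp, t, x, p0=p0, maxfev=20000)
        _, r1, _, r2, _ = popt
        r1, r2 = abs(float(r1)), abs(float(r2))
        if r1 < 1e-9 or r2 < 1e-9:
            raise RuntimeError
        m = k / (r1 * r2)
        c = m * (r1 + r2)
        tau = 2.0 * m / c
    except RuntimeError:
        # single-exponential fallback: treat as heavily overdamped spring-dashpot
        lam = np.polyfit(t, np.log(np.maximum(np.abs(centered), 1e-12)), 1)[0]
        tau = -1.0 / min(lam, -1e-9)
        c = k * tau
        m = c * tau / 2.0
    return RingdownFit(float(m), float(c), float(tau), float("nan"), True, float(centered[0]), 0.0, baseline0)


def reconstruct_force(
    positions: ArrayLike,
    probe: ProbeModel,
    mode: str = "quasistatic",
    frame_times: ArrayLike | None = None,
    fps: float | None = None,
    sg_window: int = 7,
    sg_order: int = 2,
) -> NDArray[np.float64]:
    """Reconstruct the force applied to the probe from its tracked position.

    ``quasistatic`` mode applies ``F = k x`` — the approximation used for
    behavioral-bandwidth movements, where drag and inertia are negligible.
    ``dynamic`` mode adds ``c x' + m x''`` with Savitzky–Golay smoothed
    central-difference derivatives (window 7, order 2 by default) to
    suppress frame-to-frame tracking jitter.

    Positions in µm; returns force in µN.
    """
    x = np.asarray(positions, dtype=float)
    if mode == "quasistatic":
        return probe.k * x
    if mode != "dynamic":
        raise ValueError(f"unknown mode {mode!r}")
    if x.size < 5:
        raise ValueError("dynamic mode needs at least 5 frames")
    if frame_times is not None:
        tt = np.asarray(frame_times, dtype=float)
        dts = np.diff(tt)
        if np.any(dts <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.ptp(dts) > 0.10 * np.mean(dts):
            raise ValueError("dynamic mode requires uniform frame intervals (<10% jitter)")
        dt_ms = float(np.mean(dts)) * 1000.0
    elif fps is not None:
        dt_ms = 1000.0 / fps
    else:
        raise ValueError("dynamic mode requires frame_times or fps")

    win = min(sg_window if sg_window % 2 == 1 else sg_window + 1, x.size if x.size % 2 == 1 else x.size - 1)
    order = min(sg_order, win - 1)
    v = signal.savgol_filter(x, win, order, deriv=1, delta=dt_ms)   # µm/ms
    a = signal.savgol_filter(x, win, order, deriv=2, delta=dt_ms)   # µm/ms²
    return probe.k * x + probe.c * v + probe.m * a


def displacement_to_joint_angle(displacement: ArrayLike, lever_arm: float = 417.0) -> NDArray | float:
    """Convert probe tip displacement to femur–tibia joint-angle change.

    The probe contacts the tibia a distance ``lever_arm`` (default 417 µm)
    from the joint, so a chord displacement *d* corresponds to an angular
    change ``degrees(arcsin(d / lever_arm))``.  Positive displacement =
    flexion, negative = extension.  E.g. 60 µm → ~8°, 150 µm → ~21°.

    Raises
    ------
    ValueError
        If ``|displacement| >= lever_arm`` (outside the arcsin domain).
    """
    d = np.asarray(displacement, dtype=float)
    if lever_arm <= 0:
        raise ValueError("lever_arm must be positive")
    if np.any(np.abs(d) >= lever_arm):
        raise ValueError("|displacement| must be < lever_arm")
    out = np.degrees(np.arcsin(d / lever_arm))
    return float(out) if out.ndim == 0 else out


# Handy unit facts used in reporting: 1 mg of mass weighs g·1 mg ≈ 9.81 µN.
GRAVITY_UN_PER_MG = 9.81


def weight_to_force(mass_mg: float) -> float:
    """Weight of a mass in µN (1 mg ≈ 9.81 µN ~ '10 µN' at field precision)."""
    return mass_mg * GRAVITY_UN_PER_MG


def force_as_fraction_of_weight(force_un: float, mass_mg: float = 1.0) -> float:
    """A force expressed as a percentage of an animal's weight (default 1 mg fly)."""
    return 100.0 * force_un / weight_to_force(mass_mg)
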