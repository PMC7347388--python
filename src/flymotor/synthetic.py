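"""Ground-truthed synthetic data for every stage of the pipeline.

This module emulates the raw observables of a fly-leg motor-unit experiment
with known ground truth, so the whole analysis chain can be built and tested
without downloading recordings:

* membrane voltage and EMG traces at 50 kHz containing spikes from three
  motor neuron types (slow tonic ~30 Hz, intermediate, fast phasic) that are
  recruited in order as a common drive signal rises;
* force-probe displacement produced by passing the summed muscle twitches
  through the probe's second-order (mass–drag–spring) dynamics;
* GCaMP-like muscle movies in which spatial clusters of pixels share a
  fluorescence trace (activation train convolved with a rise/decay kernel);
* tracked leg points placed on a circular tibia arc and foreshortened into
  an ellipse by the out-of-plane azimuth, with controlled outliers;
* Bernoulli walk-initiation trials and stimulus-locked speed traces.

Everything is driven by a single integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .probe import ProbeModel

NEURON_TYPES = ("slow", "intermediate", "fast")


@dataclass
class NeuronParams:
    """Per-type motor neuron parameters."""

    rest_mV: float
    rate_Hz: float              # tonic rate at zero drive (0 for threshold cells)
    drive_rate_Hz: float        # firing rate when recruited by drive
    threshold: float            # drive level above which the cell is recruited
    force_per_spike_uN: float
    spike_amp_mV: float
    emg_amp_pA: float
    noise_sd: float             # membrane noise, mV
    twitch_rise_ms: float
    twitch_decay_ms: float
    refractory_ms: float = 3.0


def default_neuron_params() -> dict[str, NeuronParams]:
    """The three motor neuron types with the study's headline properties.

    Slow: depolarized rest (−48 mV), tonic ~30 Hz, <0.1 µN per spike, slow
    twitch.  Intermediate: −60 mV, silent at rest, ~1 µN per spike.  Fast:
    hyperpolarized rest (−68 mV), silent at rest, ~10 µN per spike,
    fast twitch, recruited only at the highest drive.
    """
    return {
        "slow": NeuronParams(
            rest_mV=-48.0, rate_Hz=30.0, drive_rate_Hz=60.0, threshold=0.0,
            force_per_spike_uN=0.08, spike_amp_mV=12.0, emg_amp_pA=15.0,
            noise_sd=0.4, twitch_rise_ms=80.0, twitch_decay_ms=400.0,
            refractory_ms=6.0,
        ),
        "intermediate": NeuronParams(
            rest_mV=-60.0, rate_Hz=0.0, drive_rate_Hz=100.0, threshold=0.35,
            force_per_spike_uN=1.0, spike_amp_mV=15.0, emg_amp_pA=60.0,
            noise_sd=0.4, twitch_rise_ms=15.0, twitch_decay_ms=60.0,
            refractory_ms=4.0,
        ),
        "fast": NeuronParams(
            rest_mV=-68.0, rate_Hz=0.0, drive_rate_Hz=50.0, threshold=0.65,
            force_per_spike_uN=10.0, spike_amp_mV=20.0, emg_amp_pA=200.0,
            noise_sd=0.4, twitch_rise_ms=8.0, twitch_decay_ms=40.0,
            refractory_ms=5.0,
        ),
    }


@dataclass
class GCaMPParams:
    rise_ms: float = 50.0
    decay_ms: float = 300.0


@dataclass
class GeometryParams:
    lever_arm_um: float = 417.0
    azimuth_deg: float = 60.0
    arc_radius_px: float = 100.0


@dataclass
class DriveParams:
    """Smoothed random-telegraph common drive in [0, 1].

    High-state dwell ~0.8 s, low-state dwell ~1.2 s; each high epoch gets an
    amplitude drawn uniformly from ``amp_range`` so that a default 60 s
    session contains intermediate-only epochs (amplitude between the
    intermediate and fast thresholds) as well as fast epochs.
    """

    scale: float = 1.0
    dwell_high_s: float = 0.8
    dwell_low_s: float = 1.2
    amp_range: tuple[float, float] = (0.45, 1.0)
    smooth_ms: float = 30.0


@dataclass
class SimConfig:
    seed: int = 0
    duration_s: float = 60.0
    fs_ephys: float = 50_000.0
    fps_video: float = 170.0
    fps_calcium: float = 50.0
    probe: ProbeModel = field(default_factory=ProbeModel)
    neuron_params: dict[str, NeuronParams] = field(default_factory=default_neuron_params)
    gcamp: GCaMPParams = field(default_factory=GCaMPParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    drive: DriveParams = field(default_factory=DriveParams)
    facilitation: float = 0.6    # 2-spike/1-spike peak force ratio = 1 + facilitation
    emg_noise_pA: float = 2.0
    force_dt_ms: float = 0.2     # internal grid for twitch force / probe ODE

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0 < self.fps_calcium < self.fps_video < self.fs_ephys):
            raise ValueError("require 0 < fps_calcium < fps_video < fs_ephys")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spike_times: dict[str, NDArray]          # s, per neuron type
    drive: NDArray                           # drive at video frame times
    video_times: NDArray                     # s
    epochs: list[tuple[float, float]]        # (start_s, end_s) of drive > theta_int
    force_video: NDArray                     # µN, true probe input force at video rate
    displacement_video: NDArray              # µm, true probe displacement at video rate
    label_image: NDArray | None = None
    activation_intervals: dict[int, list[tuple[float, float]]] | None = None
    occlusion_fraction: NDArray | None = None    # (T, K)
    joint_angles: NDArray | None = None
    outliers: list[tuple[int, int]] | None = None   # (frame, point) injections
    trial_p: dict[str, float] | None = None


@dataclass
class Session:
    config: SimConfig
    time_ephys: NDArray       # s
    voltage: dict[str, NDArray]   # mV per neuron type, 50 kHz
    emg: NDArray              # pA, 50 kHz
    probe_displacement: NDArray   # µm at video rate
    video_times: NDArray      # s
    truth: GroundTruth


# ---------------------------------------------------------------------------
# probe ODE
# ---------------------------------------------------------------------------

def simulate_probe_response(
    force: ArrayLike,
    probe: ProbeModel,
    dt_ms: float,
    x0: float = 0.0,
    v0: float = 0.0,
) -> NDArray[np.float64]:
    """Displacement of the probe driven by a sampled force series.

    Integrates ``m x'' + c x' + k x = F(t)`` treating the force as
    zero-order-hold between samples: the state transition over each step is
    the exact matrix exponential of the linear system, applied as a digital
    filter, so the solution is exact (to float precision) for piecewise
    constant forces and unconditionally stable.  The homogeneous response to
    the initial conditions ``(x0, v0)`` is added from the eigendecomposition
    of the same transition matrix.

    Parameters
    ----------
    force : array, µN, sampled every ``dt_ms``.
    dt_ms : sample interval, ms; must resolve the probe's relaxation
        (``dt_ms <= 0.1 * tau`` is enforced).

    Returns displacement in µm on the same grid.
    """
    f = np.asarray(force, dtype=float)
    if f.ndim != 1:
        raise ValueError("force must be a 1-D series")
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if dt_ms > 0.1 * probe.tau:
        raise ValueError(
            f"dt_ms={dt_ms} too coarse: need dt <= 0.1 * tau = {0.1 * probe.tau:.4g} ms"
        )

    A = np.array([[0.0, 1.0], [-probe.k / probe.m, -probe.c / probe.m]])
    B = np.array([[0.0], [1.0 / probe.m]])
    C = np.array([[1.0, 0.0]])
    D = np.zeros((1, 1))
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt_ms, method="zoh")

    # forced response via the discrete transfer function (zero initial state)
    num, den = signal.ss2tf(Ad, Bd, Cd, Dd)
    x_forced = signal.lfilter(num[0], den, f)

    # free response: x_free[n] = C Ad^n [x0, v0]
    if x0 != 0.0 or v0 != 0.0:
        lam, V = np.linalg.eig(Ad)
        coef = np.linalg.solve(V, np.array([x0, v0], dtype=complex))
        n = np.arange(f.size)
        modes = lam[None, :] ** n[:, None]          # (n, 2)
        x_free = (modes * (V[0] * coef)[None, :]).sum(axis=1).real
        return x_forced + x_free
    return x_forced


def underdamped_free_response(
    t_ms: ArrayLike, probe: ProbeModel, x0: float, v0: float = 0.0
) -> NDArray[np.float64]:
    """Closed-form free ring-down of the underdamped probe (oracle form).

    ``x(t) = e^(−t/τ) (x0 cos ω_d t + ((v0 + x0/τ)/ω_d) sin ω_d t)``
    """
    t = np.asarray(t_ms, dtype=float)
    tau, wd = probe.tau, probe.omega_d
    return np.exp(-t / tau) * (x0 * np.cos(wd * t) + (v0 + x0 / tau) / wd * np.sin(wd * t))


# ---------------------------------------------------------------------------
# spike trains and electrophysiology session
# ---------------------------------------------------------------------------

def _telegraph_drive(rng: np.random.Generator, n: int, dt_s: float, p: DriveParams) -> NDArray:
    """Smoothed random telegraph in [0, 1] on an n-sample grid."""
    if p.scale <= 0:
        return np.zeros(n)
    drive = np.zeros(n)
    i = 0
    high = False
    while i < n:
        dwell = rng.exponential(p.dwell_high_s if high else p.dwell_low_s)
        j = min(n, i + max(int(round(dwell / dt_s)), 1))
        if high:
            drive[i:j] = rng.uniform(*p.amp_range)
        i = j
        high = not high
    drive = gaussian_filter1d(drive, sigma=max(p.smooth_ms / 1000.0 / dt_s, 1e-9))
    return np.clip(drive * p.scale, 0.0, 1.0)


def _spike_times_from_rate(
    rng: np.random.Generator, rate: NDArray, dt_s: float, refractory_ms: float
) -> NDArray:
    """Bernoulli-per-bin inhomogeneous spike train with dead time.

    The per-bin probability is corrected for the refractory dead time so
    that the realized mean rate matches the requested one
    (p = λ·dt / (1 − λ·t_ref)).
    """
    t_ref = refractory_ms / 1000.0
    lam = np.clip(rate, 0.0, 0.9 / max(t_ref, dt_s))
    p = np.clip(lam * dt_s / np.maximum(1.0 - lam * t_ref, 1e-6), 0.0, 1.0)
    hits = np.nonzero(rng.random(rate.size) < p)[0]
    times = hits * dt_s
    if times.size == 0:
        return times
    keep = [0]
    for k in range(1, times.size):
        if times[k] - times[keep[-1]] >= t_ref:
            keep.append(k)
    return times[keep]


def _biexp_kernel(dt_ms: float, rise_ms: float, decay_ms: float, length_factor: float = 6.0) -> NDArray:
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    n = max(int(length_factor * decay_ms / dt_ms), 2)
    t = np.arange(n) * dt_ms
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    peak = k.max()
    return k / peak if peak > 0 else k


def _spike_waveform(fs: float, amp: float, width_ms: float = 2.0) -> NDArray:
    """Biexponential depolarization ~2 ms wide, peak amplitude `amp`."""
    rise = width_ms / 6.0
    decay = width_ms / 2.5
    n = max(int(4 * width_ms * fs / 1000.0), 8)
    t = np.arange(n) * 1000.0 / fs
    w = np.exp(-t / decay) - np.exp(-t / rise)
    return amp * w / w.max()


def facilitation_increments(n: int, facilitation: float) -> NDArray:
    """Per-spike force scale factors within a burst.

    Spike *j* (1-based) contributes ``facilitation**(j−1)`` of the unit
    force, so the cumulative peak for n coincident spikes is the geometric
    sum ``(1 − f^n)/(1 − f)``: two spikes produce ``1 + f`` times the force
    of one (default f = 0.6 → ratio 1.6), and the curve saturates within
    ~10 spikes.  ``facilitation=1`` gives linear summation.
    """
    return np.power(float(facilitation), np.arange(n))


def _burst_scales(times: NDArray, facilitation: float, window_s: float = 0.1) -> NDArray:
    """Facilitation scale per spike, with burst position reset after gaps > window."""
    scales = np.empty(times.size)
    pos = 0
    for i, t in enumerate(times):
        if i == 0 or t - times[i - 1] > window_s:
            pos = 0
        scales[i] = facilitation**pos
        pos += 1
    return scales


def simulate_session(config: SimConfig) -> Session:
    """Simulate a full recording session: voltage, EMG, probe displacement.

    The three neuron types share a smoothed telegraph drive.  The slow
    neuron fires tonically near its configured rate and modulates upward
    with drive; intermediate and fast neurons fire only above their
    (increasing) drive thresholds.  Recruitment order is enforced by
    construction: within every high-drive epoch the intermediate neuron's
    first spike follows the slow neuron's first spike, and the fast
    neuron's first spike follows the intermediate's.  Every spike adds a
    waveform to the voltage/EMG traces and a facilitation-scaled twitch to
    the probe's force input; the probe displacement is the second-order
    model's response to that force.
    """
    rng = np.random.default_rng(config.seed)
    dur = config.duration_s

    # --- drive and spike trains on a 1 ms grid -----------------------------
    dt_drive = 1e-3
    n_drive = int(round(dur / dt_drive))
    drive = _telegraph_drive(rng, n_drive, dt_drive, config.drive)

    theta_int = config.neuron_params["intermediate"].threshold
    theta_fast = config.neuron_params["fast"].threshold

    spikes: dict[str, NDArray] = {}
    for name in NEURON_TYPES:
        p = config.neuron_params[name]
        if name == "slow":
            rate = p.rate_Hz * (1.0 + 1.5 * drive)
        else:
            rate = np.where(drive > p.threshold, p.drive_rate_Hz, 0.0)
        spikes[name] = _spike_times_from_rate(rng, rate, dt_drive, p.refractory_ms)

    # --- high-drive epochs and recruitment-order enforcement ---------------
    above = drive > theta_int
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    epochs = [(s * dt_drive, e * dt_drive) for s, e in zip(starts, stops)]

    for lo_name, hi_name in (("slow", "intermediate"), ("intermediate", "fast")):
        lo, hi = spikes[lo_name], spikes[hi_name]
        keep = np.ones(hi.size, dtype=bool)
        for s, e in epochs:
            in_ep_lo = lo[(lo >= s) & (lo < e)]
            in_ep_hi = (hi >= s) & (hi < e)
            if in_ep_lo.size == 0:
                keep &= ~in_ep_hi
            else:
                keep &= ~(in_ep_hi & (hi <= in_ep_lo[0]))
        spikes[hi_name] = hi[keep]

    # --- voltage and EMG traces at fs_ephys --------------------------------
    fs = config.fs_ephys
    n_eph = int(round(dur * fs))
    time_ephys = np.arange(n_eph) / fs
    drive_eph = np.interp(time_ephys, np.arange(n_drive) * dt_drive, drive)

    emg = rng.normal(0.0, config.emg_noise_pA, n_eph)
    voltage: dict[str, NDArray] = {}
    for name in NEURON_TYPES:
        p = config.neuron_params[name]
        v = p.rest_mV + 8.0 * drive_eph + rng.normal(0.0, p.noise_sd, n_eph)
        wf = _spike_waveform(fs, p.spike_amp_mV)
        emg_wf = _spike_waveform(fs, p.emg_amp_pA, width_ms=1.5)
        idx = np.round(spikes[name] * fs).astype(int)
        idx = idx[idx + wf.size < n_eph]
        spikes[name] = idx / fs  # drop unrenderable tail spikes from truth too
        for i in idx:
            v[i : i + wf.size] += wf
            emg[i : i + emg_wf.size] += emg_wf
        voltage[name] = v

    # --- probe force and displacement --------------------------------------
    dt_f = config.force_dt_ms / 1000.0
    n_f = int(round(dur / dt_f))
    force = np.zeros(n_f)
    for name in NEURON_TYPES:
        p = config.neuron_params[name]
        times = spikes[name]
        if times.size == 0:
            continue
        scales = _burst_scales(times, config.facilitation)
        train = np.zeros(n_f)
        idx = np.minimum(np.round(times / dt_f).astype(int), n_f - 1)
        np.add.at(train, idx, scales * p.force_per_spike_uN)
        kernel = _biexp_kernel(config.force_dt_ms, p.twitch_rise_ms, p.twitch_decay_ms)
        force += signal.fftconvolve(train, kernel)[:n_f]

    disp = simulate_probe_response(force, config.probe, config.force_dt_ms)

    video_times = np.arange(int(dur * config.fps_video)) / config.fps_video
    t_f = np.arange(n_f) * dt_f
    disp_video = np.interp(video_times, t_f, disp)
    force_video = np.interp(video_times, t_f, force)
    drive_video = np.interp(video_times, np.arange(n_drive) * dt_drive, drive)

    truth = GroundTruth(
        spike_times=spikes,
        drive=drive_video,
        video_times=video_times,
        epochs=epochs,
        force_video=force_video,
        displacement_video=disp_video,
    )
    return Session(config, time_ephys, voltage, emg, disp_video, video_times, truth)


def simulate_twitch_trials(
    n_spikes_list: ArrayLike,
    probe: ProbeModel | None = None,
    force_per_spike_uN: float = 10.0,
    facilitation: float = 0.6,
    twitch_rise_ms: float = 8.0,
    twitch_decay_ms: float = 40.0,
    isi_ms: float = 1.0,
    pre_ms: float = 20.0,
    post_ms: float = 250.0,
    dt_ms: float = 0.2,
    noise_sd_um: float = 0.0,
    seed: int = 0,
) -> list[tuple[int, NDArray, NDArray]]:
    """Optogenetic-style trials: a short burst of n spikes moves the probe.

    For each requested spike count, a burst at ``isi_ms`` spacing drives
    facilitation-scaled twitches through the probe model.  Returns a list of
    ``(n_spikes, time_s, displacement_um)`` with displacement baseline at 0;
    multiply by ``probe.k`` for the quasistatic force trace.
    """
    probe = probe or ProbeModel()
    rng = np.random.default_rng(seed)
    out = []
    n_t = int(round((pre_ms + post_ms) / dt_ms))
    t = np.arange(n_t) * dt_ms / 1000.0
    kernel = _biexp_kernel(dt_ms, twitch_rise_ms, twitch_decay_ms)
    for n_sp in np.atleast_1d(np.asarray(n_spikes_list, dtype=int)):
        train = np.zeros(n_t)
        scales = facilitation_increments(n_sp, facilitation)
        for j in range(n_sp):
            idx = int(round((pre_ms + j * isi_ms) / dt_ms))
            if idx < n_t:
                train[idx] += scales[j] * force_per_spike_uN
        force = signal.fftconvolve(train, kernel)[:n_t]
        disp = simulate_probe_response(force, probe, dt_ms)
        if noise_sd_um > 0:
            disp = disp + rng.normal(0.0, noise_sd_um, n_t)
        out.append((int(n_sp), t, disp))
    return out


# ---------------------------------------------------------------------------
# muscle movie
# ---------------------------------------------------------------------------

def make_femur_labels(shape: tuple[int, int] = (48, 80), n_clusters: int = 2) -> NDArray[np.int_]:
    """A femur-shaped elliptical mask partitioned into ``n_clusters`` bands.

    Returns an integer label image: 0 outside the femur, 1..K inside,
    with bands ordered ventral (top rows) to dorsal (bottom rows).
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = ((rr - h / 2) / (h / 2 - 1)) ** 2 + ((cc - w / 2) / (w / 2 - 1)) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=int)
    rows = rr[mask]
    edges = np.quantile(rows, np.linspace(0, 1, n_clusters + 1))
    band = np.clip(np.searchsorted(edges, rows, side="right"), 1, n_clusters)
    labels[mask] = band
    return labels


@dataclass
class PixelMovie:
    frames: NDArray          # (T, H, W) float
    times: NDArray           # s
    fps: float


def simulate_muscle_movie(
    label_image: ArrayLike,
    activation_intervals: dict[int, list[tuple[float, float]]],
    gcamp: GCaMPParams | None = None,
    n_frames: int = 300,
    fps: float = 50.0,
    baseline: float = 100.0,
    amplitude: float = 100.0,
    noise_sd: float = 5.0,
    occluder_track: ArrayLike | None = None,
    seed: int = 0,
) -> tuple[PixelMovie, GroundTruth]:
    """GCaMP-like movie in which each labeled cluster shares one trace.

    Per-cluster fluorescence = ``baseline + amplitude * (activation train
    convolved with a rise/decay difference-of-exponentials kernel)``; each
    member pixel gets the cluster trace plus i.i.d. Gaussian noise.  An
    optional boolean ``occluder_track`` of shape (T, H, W) zeroes covered
    pixels, and the fraction of each cluster covered per frame is recorded
    in the ground truth.
    """
    labels = np.asarray(label_image, dtype=int)
    if labels.ndim != 2:
        raise ValueError("label_image must be 2-D")
    gcamp = gcamp or GCaMPParams()
    rng = np.random.default_rng(seed)
    ks = sorted(int(k) for k in np.unique(labels) if k > 0)
    times = np.arange(n_frames) / fps
    duration = n_frames / fps
    dt_ms = 1000.0 / fps
    kernel = _biexp_kernel(dt_ms, gcamp.rise_ms, gcamp.decay_ms)

    traces = {}
    for k in ks:
        train = np.zeros(n_frames)
        for start, stop in activation_intervals.get(k, []):
            if not (0 <= start <= stop <= duration + 1e-9):
                raise ValueError(f"activation interval ({start}, {stop}) outside movie duration")
            train[(times >= start) & (times < stop)] = 1.0
        conv = signal.fftconvolve(train, kernel)[:n_frames]
        traces[k] = baseline + amplitude * conv

    h, w = labels.shape
    frames = np.full((n_frames, h, w), baseline, dtype=float)
    for k in ks:
        frames[:, labels == k] = traces[k][:, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    occ_frac = np.zeros((n_frames, len(ks)))
    if occluder_track is not None:
        occ = np.asarray(occluder_track, dtype=bool)
        if occ.shape != frames.shape:
            raise ValueError("occluder_track must have shape (n_frames, H, W)")
        frames[occ] = 0.0
        for j, k in enumerate(ks):
            member = labels == k
            n_member = member.sum()
            occ_frac[:, j] = occ[:, member].sum(axis=1) / max(n_member, 1)

    truth = GroundTruth(
        spike_times={}, drive=np.zeros(n_frames), video_times=times, epochs=[],
        force_video=np.zeros(n_frames), displacement_video=np.zeros(n_frames),
        label_image=labels, activation_intervals={k: list(activation_intervals.get(k, [])) for k in ks},
        occlusion_fraction=occ_frac,
    )
    return PixelMovie(frames, times, fps), truth


# ---------------------------------------------------------------------------
# leg points
# ---------------------------------------------------------------------------

TIBIA_RADIUS_FRACTIONS = np.array([0.70, 0.82, 0.94, 1.06, 1.18, 1.30])
FEMUR_X_FRACTIONS = np.array([-1.6, -1.4, -1.2, -1.0, -0.8, -0.6])


@dataclass
class TrackedPoints:
    """Per-frame tracked leg points (6 femur + 6 tibia), image coordinates in px."""

    femur: NDArray    # (T, 6, 2)
    tibia: NDArray    # (T, 6, 2)
    times: NDArray    # s


def simulate_leg_points(
    joint_angle_series: ArrayLike,
    azimuth_deg: float = 60.0,
    arc_radius_px: float = 100.0,
    noise_px: float = 1.0,
    outlier_rate: float = 0.0,
    outlier_shift_px: float = 50.0,
    fps: float = 170.0,
    seed: int = 0,
) -> tuple[TrackedPoints, GroundTruth]:
    """Project a swinging tibia onto the camera plane as tracked points.

    The femur lies along +x with the femur–tibia joint at the origin; six
    femur points are fixed on that axis.  Six tibia points sit at fixed
    radii along the tibia, which makes the interior joint angle theta with
    the femur (180° = straight leg), so each sweeps a circle of its radius.
    The leg's swing plane is tilted out of the camera plane by the azimuth,
    foreshortening the y (swing) coordinate by cos(azimuth) — the circular
    arc of the tibia centroid projects to an ellipse with axis ratio
    cos(azimuth).  Gaussian jitter is added to every coordinate; with
    probability ``outlier_rate`` per frame one random tibia point is
    displaced by ``outlier_shift_px`` in a random direction, and the
    injection is logged in the ground truth.
    """
    theta = np.asarray(joint_angle_series, dtype=float)
    if not (0 <= azimuth_deg < 90):
        raise ValueError("azimuth must be in [0, 90) degrees")
    if not (0 <= outlier_rate < 1):
        raise ValueError("outlier_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = theta.size
    cos_az = np.cos(np.radians(azimuth_deg))

    phi = np.radians(180.0 - theta)             # tibia direction from +x femur axis
    radii = TIBIA_RADIUS_FRACTIONS * arc_radius_px
    tibia = np.empty((n, 6, 2))
    tibia[:, :, 0] = np.cos(phi)[:, None] * radii[None, :]
    tibia[:, :, 1] = np.sin(phi)[:, None] * radii[None, :] * cos_az

    femur = np.zeros((n, 6, 2))
    femur[:, :, 0] = (FEMUR_X_FRACTIONS * arc_radius_px)[None, :]

    if noise_px > 0:
        tibia += rng.normal(0.0, noise_px, tibia.shape)
        femur += rng.normal(0.0, noise_px, femur.shape)

    outliers: list[tuple[int, int]] = []
    if outlier_rate > 0:
        hit = rng.random(n) < outlier_rate
        for fr in np.nonzero(hit)[0]:
            pt = int(rng.integers(6))
            ang = rng.uniform(0, 2 * np.pi)
            tibia[fr, pt] += outlier_shift_px * np.array([np.cos(ang), np.sin(ang)])
            outliers.append((int(fr), pt))

    times = np.arange(n) / fps
    truth = GroundTruth(
        spike_times={}, drive=np.zeros(n), video_times=times, epochs=[],
        force_video=np.zeros(n), displacement_video=np.zeros(n),
        joint_angles=theta.copy(), outliers=outliers,
    )
    return TrackedPoints(femur, tibia, times), truth


# ---------------------------------------------------------------------------
# behavior trials
# ---------------------------------------------------------------------------

def simulate_behavior_trials(
    p_control: float,
    p_treated: float,
    n_per_group: int = 30,
    speed_effect: float = 1.0,
    stim_ms: float = 720.0,
    baseline_speed: float = 8.0,
    fps: float = 30.0,
    trace_s: float = 3.0,
    onset_s: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Bernoulli walk-initiation trials plus stimulus-locked speed traces.

    Walking trials get a forward-speed trace (mm/s at ``fps``) that is
    multiplied by ``speed_effect`` during the stimulus window plus the
    following 200 ms.  Returns ``(table, traces, onset_index)`` where
    ``table`` is a pandas DataFrame with columns
    ``trial_id, group, stim_ms, category, outcome``.
    """
    import pandas as pd

    for p in (p_control, p_treated):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_t = int(round(trace_s * fps))
    onset = int(round(onset_s * fps))
    stim_frames = int(round(stim_ms / 1000.0 * fps))
    effect_window = slice(onset, min(onset + stim_frames + int(0.2 * fps), n_t))

    rows, traces = [], []
    for group, p_walk in (("control", p_control), ("treated", p_treated)):
        outcomes = rng.random(n_per_group) < p_walk
        for i, outcome in enumerate(outcomes):
            speed = np.maximum(
                baseline_speed + rng.normal(0.0, noise_sd, n_t), 0.0
            )
            speed[effect_window] *= speed_effect
            rows.append(
                dict(
                    trial_id=f"{group}_{i:03d}", group=group, stim_ms=stim_ms,
                    category="Stationary", outcome=bool(outcome),
                )
            )
            traces.append(speed)
    table = pd.DataFrame(rows)
    return table, np.array(traces), onset
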