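# Methods notes

This note records the models, parameter choices, and numerical decisions
behind `flymotor`, and what the synthetic benchmarks do and do not
establish about real recordings.

## Units

Forces in µN, displacements in µm, time in ms (so 1 µN = 1 mg·µm/ms²),
masses in mg and drag in mg/ms. The probe's drag coefficient is
`c = 0.1377 mg/ms`, equivalent to 1.377·10⁻⁴ kg/s; quoting the same
number in kg/s would be dimensionally inconsistent with the observed
~2.5 ms relaxation, so mg/ms is the package's canonical unit and all
derived quantities (τ = 2m/c ≈ 2.47 ms, damped period ≈ 5.86 ms) follow
from it.

## Force probe

**Model.** `F = m x'' + c x' + k x`, underdamped for the default
parameters (k = 0.2234 µN/µm, m = 0.1702 mg, c = 0.1377 mg/ms).

**Integration.** The probe is a linear time-invariant system, so
`simulate_probe_response` uses exact zero-order-hold discretization: the
state-transition matrix over one sample step is the matrix exponential of
the continuous system, applied as a digital filter, and the response to
initial conditions is added from the eigendecomposition of the same
matrix. This is exact (to float precision) for piecewise-constant force
inputs and unconditionally stable, which a fixed-step explicit integrator
is not. The input must still resolve the probe's dynamics: sample steps
coarser than 0.1·τ (≈0.25 ms) are rejected, and session simulation builds
its force input on a 0.2 ms grid before decimating displacement to the
video rate.

**Ring-down fitting.** `fit_flick_dynamics` fits the closed-form
underdamped free response `A e^(−t/τ) cos(ω_d t + φ) + b` by nonlinear
least squares (frequency seeded from the FFT peak), then reports
`m = k/(ω_d² + 1/τ²)` and `c = 2m/τ` — so the fitted (m, c) reproduce the
fitted (τ, ω_d) identically. Traces that never cross baseline after
release are flagged overdamped and fitted as a biexponential, with m, c
derived from the two real decay rates.

**Force reconstruction.** Quasistatic mode is `F = k x`; dynamic mode
adds drag and inertia using Savitzky–Golay derivatives (window 7,
order 2) to suppress tracking jitter. At behavioral bandwidths (<50 Hz)
the two differ by <2 % RMS, which is why the quasistatic approximation is
the default for spontaneous movements.

**Probe tracking.** The frame is resampled (bilinear) along the probe's
travel axis into a band-averaged intensity profile; the baseline is the
profile median (robust to bright clutter) and the position is the
centroid of the contiguous above-half-maximum run around the peak,
weighted relative to the half-maximum level. Weighting relative to
baseline instead would introduce a truncation bias of ~0.2 px for
Gaussian-like bands. Frames with no peak above baseline return NaN with
zero quality rather than raising.

**Angle conversion.** `degrees(arcsin(d / lever_arm))` with the 417 µm
default lever arm. Over the working range (|d| ≤ 150 µm) arcsin, arctan
and the small-angle approximation agree within 0.5°; arcsin is the chord
geometry and reproduces the conventional roundings (60 µm → 8°,
75 µm → 10°, 150 µm → 21°).

## Spike detection

The detector band-passes the trace's first derivative (3-pole Butterworth
high-pass 209 Hz, then low-pass 898 Hz, both causal). Causal filtering is
deliberate: zero-phase filtering would shift event latencies and corrupt
soma→EMG conduction-delay measurements. Candidates are filtered-trace
peaks above threshold with ≥1 ms separation (fly spikes are ~2 ms wide);
the default threshold is 5× the robust (MAD-based) s.d. of the filtered
trace.

Shape scoring uses full unconstrained DTW with squared local cost over a
251-sample window; no Sakoe–Chiba band is applied, since at 50 kHz the
relevant time shifts (tens of samples) are a large fraction of plausible
band widths. The amplitude score is the raw-trace peak within ±1 ms of
the candidate minus the median 1.25–2.5 ms before it — keeping the
measurement local so that neighboring spikes within the 5 ms window do
not contaminate it.

Acceptance requires template-like shape AND large amplitude. When cutoffs
are not supplied, a 2-component Gaussian mixture on (log distance,
amplitude) classifies the candidates and the accepted component's
extremes become the cutoffs; in practice cutoffs should be established
per cell on a spiking trace and then applied as fixed values. Template
estimation averages peak-aligned windows with one refinement pass that
drops events above the 90th percentile of DTW distance to the mean.

Onsets are the argmax of the 5-sample-smoothed second difference in the
half-window preceding the peak — the point of maximum acceleration at the
spike foot. EMG traces with negative-going events are handled by the
`invert` flag (the detector operates on the negated trace).

## Muscle clusters

Pixel time series are z-scored so Euclidean k-means is monotone in
1 − Pearson correlation; zero-variance pixels are dropped first. Five
seeded restarts are run and the best inertia kept; labels are renumbered
by centroid position (ventral→dorsal) so cluster numbers are stable
across runs. K defaults to 6, the granularity at which fly femur movies
segment repeatably.

Map refinement smooths each cluster's indicator with a Gaussian
(σ = 2 px, a choice — only the 0.75 support threshold is canonical) and
keeps pixels with support ≥ 0.75. ΔF/F uses F0 = the 10th percentile of
the cluster's valid trace; a percentile baseline is robust when the
recording is dominated by activity. Frames where an occluder covers >40 %
of a cluster's pixels are invalid for that cluster; below that, the trace
is computed from the visible pixels only.

Activation detection Savitzky–Golay-filters the ΔF/F trace with a
simultaneous derivative (defaults: polynomial order 7, frame length 9 —
the convention is ambiguous, so both are configurable) and interpolates
onto the video grid. Because indicator decay is slow relative to leg
movements, negative derivatives are noise; their RMS sets the noise
scale, and activations are runs of derivative > 2× that scale.

## Kinematics

Outliers among the six tibia points are detected from the pooled
per-frame nearest-neighbor distance distribution (threshold: median +
5 × 1.4826·MAD). A single outlying point is re-placed by least squares
against target distances drawn from the per-pair empirical distance
distributions and flagged; frames with ≥2 outlying points are excluded.
Coordinates are median-filtered over 5 frames (a choice; the filter is
configurable) before the centroid is taken.

The centroid ellipse is fitted by the Halir–Flusser direct least-squares
conic (via `skimage.measure.EllipseModel`) — stable and closed-form.
Azimuth = arccos(b/a). Joint angles are measured after dividing the
minor-axis coordinate by cos(azimuth) (mapping the ellipse back to the
circular arc), relative to the femur axis direction, with 180° = straight
leg. Centroids whose unprojected radius deviates from the arc by more
than 3 robust s.d. are flagged. Fits require ≥20 frames spanning ≥60° of
arc; degenerate (collinear) inputs raise.

## Recruitment statistics

Spike-triggered histograms collect frames in (spike, spike + 25 ms]; at
170 Hz that is ~4 frames per spike. Frames in overlapping windows count
once per contributing window by default (`count_once=True` collapses
them); the centroid is the mass-weighted mean of the raw counts, computed
before any log scaling used for display. Probe velocity comes from a
Savitzky–Golay derivative (window 5, order 2) at the video rate.
Stationary "hotspot" bins (probe at rest or at full pull) can be masked
via `exclude_mask`. The force-per-spike curve averages aligned trials per
spike count, takes peaks, and fits a free-intercept line; the 2:1 ratio
is reported when both counts are present.

## Behavior statistics

Percent speed change treats the stimulus-onset sample as the baseline and
averages strictly after it through stimulus + 200 ms. Walk initiation
requires speed > 3 mm/s for ≥50 % of the 500 ms post-onset window
("sustained" is operationalized as a fraction; configurable). The
bootstrap pools both groups, redraws group-sized samples with
replacement, and takes the two-tailed p as the fraction of draws whose
absolute difference is at least the observed one, with add-one smoothing
(count + 1)/(draws + 1) so p is never exactly 0. Resampling is flat
across trials; per-fly block structure, if present in real data, is not
modeled. The Benjamini–Hochberg step-up is implemented directly and
cross-checked in the tests against both a brute-force evaluation of its
definition and `statsmodels.multipletests`.

## Synthetic data generator

The generator fixes all randomness with a single seed (identical seeds
give bit-identical outputs) and records every latent quantity as ground
truth.

**Neuron parameters** (defaults): slow — rest −48 mV, tonic 30 Hz,
0.08 µN/spike, slow twitch (80/400 ms rise/decay), 6 ms refractory;
intermediate — rest −60 mV, silent at rest, recruited above drive 0.35 at
100 Hz, 1 µN/spike (15/60 ms twitch); fast — rest −68 mV, recruited above
drive 0.65 at 50 Hz, 10 µN/spike (8/40 ms twitch). Spike waveforms are
~2 ms biexponential depolarizations; EMG events scale 15/60/200 pA across
the three types.

**Drive.** A smoothed random telegraph (high dwell ~0.8 s, low ~1.2 s,
30 ms Gaussian smoothing); each high epoch draws an amplitude from
U(0.45, 1.0), so a 60 s session contains both intermediate-only and fast
epochs. Recruitment order holds by construction: within each high-drive
epoch, intermediate spikes preceding the slow neuron's first spike are
removed, and fast spikes preceding the intermediate's first spike are
removed. Spike trains are Bernoulli-per-millisecond with a dead time;
per-bin probabilities are corrected for the dead time so realized rates
match the nominal ones.

**Force and facilitation.** Each spike contributes a twitch kernel
(difference of exponentials) scaled by `facilitation^(position-in-burst)`;
with the default 0.6 the cumulative peak is the geometric sum, so two
spikes produce 1.6× one spike's force and the curve saturates within ~10
spikes. Setting facilitation to 1 yields linear summation. Slow-fiber
twitch kinetics in the fly are not quantitatively established; the slow
time constants here are configurable stand-ins.

**GCaMP movies.** Cluster fluorescence = baseline + amplitude × (binary
activation train ⊗ rise-50 ms/decay-300 ms kernel); pixels add i.i.d.
Gaussian noise; an optional occluder zeroes covered pixels and its
coverage fraction is logged per cluster and frame.

**Leg points.** Six femur points on the +x axis, six tibia points at
fixed radii (0.70–1.30 × the 100 px arc radius, so the centroid circle
radius equals the nominal radius); the swing-plane y-coordinate is
foreshortened by cos(azimuth); Gaussian jitter everywhere; with
per-frame probability `outlier_rate` one random tibia point is displaced
50 px and logged.

**What the benchmarks do not show.** The generator has no motion
artifacts, no photobleaching, no correlated pixel noise, no
slow-drifting baselines, no electrode drift or seal instability, no
cross-talk between EMG units with variable waveform polarity, and its
spikes are homogeneous within a type. Perfect recall/precision and
ARI = 1 on these data demonstrate correctness of the algorithms under
their stated assumptions, not expected performance on real recordings;
real data will require per-cell cutoffs and will degrade gracefully
rather than remaining at ceiling.

## Problem sizes

Unit tests use 5–30 s sessions and a few hundred movie frames; the
end-to-end recovery checks use 60 s sessions at the full 50 kHz rate, 100
calibration replicates, 20 session seeds for the recruitment-ordering
sign test, and 1000 replicate experiments for bootstrap type-I
calibration — sizes at which all estimates are stable while the whole
suite runs in well under a minute of compute plus JIT warm-up.
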