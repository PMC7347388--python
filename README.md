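# flymotor

Analysis tools for motor-unit recruitment in the *Drosophila* leg.

Fly tibia flexion is controlled by a small pool of motor neurons spanning
three functional classes — *slow* (tonically active, <0.1 µN per spike),
*intermediate* (~1 µN per spike), and *fast* (~10 µN per spike, roughly the
weight of the fly) — that are recruited in order of increasing force
capacity, a size-principle-like hierarchy. Measuring that hierarchy
requires a chain of bespoke computations, all implemented here:

* **Force-probe physics** (`flymotor.probe`). The fly pulls on a flexible
  calibrated fiber modeled as a damped harmonic oscillator,
  `F = m x'' + c x' + k x` (µN, µm, ms; `k = 0.2234 µN/µm`,
  `m = 0.1702 mg`, `c = 0.1377 mg/ms`). Includes probe tracking in video
  frames, spring-constant calibration by OLS, ring-down ("flick") fitting
  for `m` and `c`, quasistatic/dynamic force reconstruction, and
  displacement→joint-angle conversion via `arcsin(d / lever_arm)` with a
  417 µm lever arm.
* **Muscle calcium clusters** (`flymotor.clusters`). K-means over pixel
  time series with a correlation metric segments GCaMP movies of the femur
  into motor-unit territories; a smoothed-support rule (threshold 0.75)
  cleans the map; per-cluster ΔF/F traces honor a >40 % occlusion
  exclusion; activations are detected where the Savitzky–Golay derivative
  exceeds twice the noise s.d. estimated from negative derivatives.
* **Spike detection** (`flymotor.spikes`). A four-step template detector
  for 50 kHz whole-cell and EMG traces: band-passed derivative (3-pole
  Butterworth, 209/898 Hz), thresholded peaks, dynamic-time-warping shape
  distance to a per-cell template over a 251-sample window, and a joint
  shape/amplitude acceptance rule. Spike onsets are located at the peak of
  the smoothed second derivative.
* **Leg kinematics** (`flymotor.kinematics`). Tracked tibia points are
  cleaned (nearest-neighbor outlier repair, median filter), the centroid
  ellipse is fitted (direct least squares), the swing-plane azimuth is
  `arccos(b/a)`, and true joint angles are recovered by unprojection
  (extended > 120°, flexed < 30°).
* **Recruitment statistics** (`flymotor.recruitment`). Spike-triggered 2-D
  histograms of probe force and velocity in the 25 ms after each spike
  (with mass-weighted centroids), firing rates in the 30 ms preceding
  another neuron's spikes, and force-per-spike curves with the
  two-spike/one-spike facilitation ratio.
* **Behavioral statistics** (`flymotor.behavior`). Percent speed change
  around optogenetic stimuli, sustained walk-initiation calls (>3 mm/s in
  the following 500 ms), pooled two-sample bootstrap (10,000 draws,
  two-tailed) and Benjamini–Hochberg FDR control.
* **Synthetic data** (`flymotor.synthetic`). Ground-truthed generators for
  every input: recruitment-structured spike trains driving voltage/EMG
  traces and probe displacement through the oscillator model, GCaMP-like
  cluster movies, elliptically projected leg arcs, and Bernoulli behavior
  trials. All generators are seeded and bit-reproducible.

## Worked example

```python
import numpy as np
from flymotor import ProbeModel, SimConfig, simulate_session, SpikeDetectParams
from flymotor.spikes import preprocess, estimate_template, detect_spikes, match_spike_trains
from flymotor.recruitment import spike_triggered_hist, probe_velocity, preceding_firing_rate

p = ProbeModel()
print(f"tau = {p.tau:.2f} ms, period = {p.period:.2f} ms")

ses = simulate_session(SimConfig(seed=0, duration_s=60.0))
tr = ses.truth
vel = probe_velocity(tr.displacement_video, 170.0)
for name in ("slow", "intermediate", "fast"):
    params = SpikeDetectParams()
    f = preprocess(ses.voltage[name], params)
    idx = np.round(tr.spike_times[name][:20] * 50000).astype(int)
    seeds = np.array([i + np.argmax(f[i:i + 120]) for i in idx])
    template = estimate_template(f, seeds, params.window)
    train = detect_spikes(ses.voltage[name], template, params)
    rec, prec = match_spike_trains(train.times, tr.spike_times[name], tol_s=1e-3)
    h = spike_triggered_hist(train.times, tr.force_video, vel, tr.video_times)
    print(f"{name:13s} detected={len(train):4d} recall={rec:.3f} "
          f"precision={prec:.3f} centroid_force={h.centroid[0]:.2f} uN")
pr = preceding_firing_rate(tr.spike_times["slow"], tr.spike_times["fast"], 30.0)
print(f"slow rate before fast spikes: {pr:.1f} Hz "
      f"vs session mean {tr.spike_times['slow'].size / 60:.1f} Hz")
```

prints

```
tau = 2.47 ms, period = 5.86 ms
slow          detected=2692 recall=1.000 precision=1.000 centroid_force=1.00 uN
intermediate  detected=2578 recall=1.000 precision=1.000 centroid_force=1.49 uN
fast          detected= 687 recall=1.000 precision=1.000 centroid_force=2.58 uN
slow rate before fast spikes: 73.5 Hz vs session mean 44.9 Hz
```

The probe's free ring-down decays with τ = 2m/c ≈ 2.5 ms and oscillates
with a ≈ 5.9 ms period, so it tracks behavior quasistatically at 170 Hz
video rates. Spike detection is essentially perfect on default synthetic
sessions, the spike-triggered centroid force is ordered
fast > intermediate > slow, and the slow neuron fires well above its
session-mean rate in the 30 ms before each fast spike — the signature of
orderly recruitment.

A thin CLI mirrors the library: `flymotor simulate|probe|spikes|clusters|
kinematics|behavior --help`.

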