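# Methods

This note documents the models, parameter choices and numerical conventions
behind `finstart`, and what the synthetic validation does and does not show.

## Sensor model and units

The data model assumes a rigid body-mounted 9-axis tag sampling all
channels synchronously at a fixed rate (default 500 Hz, the rate the
package's calibration constants refer to). Raw 16-bit counts map linearly
to physical units, `value = counts × full-scale-range / 32768`, with
defaults ±16 g (accelerometer), ±1500 deg s⁻¹ (gyroscope) and ±1.0 Gauss
(magnetometer); g → m s⁻² uses standard gravity 9.80665. Out-of-range
samples are *flagged* as clipped rather than rejected: fast-starts
plausibly saturate a ±16 g accelerometer, and discarding them would bias
exactly the events of interest.

Body-frame axis semantics are fixed package-wide: **x lateral** (rotation
about x = pitch), **y forward**, **z dorso-ventral** (rotation about z =
yaw). A level tag at rest reads ≈ −g on its z acceleration channel; this
sign convention propagates through the gravity model (earth frame z-up,
gravity vector (0, 0, −g)).

Angular velocity is kept in deg s⁻¹ throughout the data model and
converted to rad s⁻¹ only inside the attitude integrator.

## Orientation filter

Attitude is a per-sample unit quaternion (sensor → earth) advanced by a
gradient-descent MARG filter: the quaternion rate from the gyroscope is
corrected by −β × the normalised gradient of an objective aligning (a) the
predicted gravity direction with the normalised accelerometer sample and
(b) a predicted earth-frame magnetic reference with the normalised
magnetometer sample. The magnetic reference is recomputed each step from
the rotated measurement (horizontal norm + vertical component), which
absorbs the local dip angle without a site constant and makes the filter
invariant to uniform magnetic-field scaling.

* **β (default 0.1, dimensionless).** Trades gyro drift against
  acceleration disturbance. β = 0 reduces exactly to quaternion
  dead-reckoning (asserted to 1e−12/step against an independent
  Ω-matrix integrator in the tests); large β with static input converges
  to the accelerometer/magnetometer attitude. 0.1 is a conventional MARG
  default for ~100–500 Hz sampling; it is config-exposed because the right
  value depends on how violently the animal accelerates.
* **Initialisation (default first 0.5 s).** An e-compass/TRIAD
  construction on the time-averaged accelerometer and magnetometer
  vectors, assuming the window is quasi-static. Degenerate inputs
  (zero-norm mean vectors, field parallel to gravity) raise explicit
  errors.
* **Convergence envelope.** The normalised-gradient correction moves
  attitude at ≈ 2β rad s⁻¹, so an initial error θ needs ≳ θ/(2β) seconds
  of static data; the test suite verifies < 1° residual from a 30° error
  after 5 s at β = 0.1, which is inside that envelope.

Gravity in the sensor frame is the rotated earth gravity vector (norm
exactly g every sample), and dynamic acceleration is defined as
`acc_measured − gravity`, so the decomposition is additive to rounding
error by construction.

## Detection

Detection thresholds the sample SD (n−1 denominator, matching the
inferential statistics used elsewhere) of MA or MG over a sliding window:

* **window 1.0 s, stride 1 sample** — the window is the analysis-segment
  length; SD values are indexed at window centres.
* **thresholds** — defaults 5.16 m s⁻² (MA) and 129.32 deg s⁻¹ (MG), the
  values a depth-1 gain-ratio tree learns from labelled fast-start vs
  routine windows in the calibration experiments;
  `detection_threshold_from_tree` re-derives them from any labelled SD
  sample.
* **refractory 1.0 s** — super-threshold runs closer than this merge,
  keeping the larger MA peak. The calibration data had stimuli minutes
  apart, so the merge rule is unconstrained there; the window length is
  the natural scale.
* MA is computed on **raw** measured acceleration: windowed SD is
  insensitive to the quasi-constant gravity component (asserted as an
  offset-invariance property test), and this keeps detection independent
  of the fusion stage. A flag allows dynamic-acceleration MA.

Event segments are fixed-length excerpts centred on the MA peak; segments
that would overrun the recording are errors (no padding — a padded segment
would not be homogeneous data). Routine segments are drawn
seeded-randomly from sub-threshold stretches, non-overlapping and clear of
event windows, to mirror the balanced FS/routine design of the calibration
experiments (whose routine windows were video-verified dash movements —
the seeded draw is the synthetic substitute for that manual step).

## Features

Per 1-s segment, per axis, per sensor: Max, Range, Mean, SD, RMS.
**Max is the signed maximum** — published Range ≈ 1.5–1.8 × Max values are
consistent with signed extrema of asymmetric signals, and a `abs_max` flag
covers the alternative reading. Inter-axial variables are exact
differences of the parent statistics (x−y, y−z, x−z), asserted to be exact
recomputations in the tests. The Gx-vs-Gy mean difference is named
`DiffMeanGxGy` (the conventional table of abbreviations carries a
typographical duplicate of `DiffMeanGxGz` for that row).

Variants: `acc-only` uses raw acceleration (gravity deliberately retained:
removing it by smoothing/filtering would make the variables depend on the
filter settings), `gyro-only` uses angular velocity, `all-combined` uses
fused dynamic acceleration + angular velocity. Gyro features are
identical across variants since fusion never touches that channel.

## Screening and feature selection

Per feature: Anderson-Darling normality (5% level, estimated parameters,
small-sample-corrected critical values, per scipy) on each class; Welch's
t iff both pass, else the **unpaired rank-sum (Mann-Whitney) test** with
normal approximation and tie correction. The calibration study names the
signed-rank test, but a signed-rank test requires paired observations and
escape/feeding/routine groups are independent with unequal sizes; the
unpaired test is the coherent choice, and a `paired` flag restores the
signed-rank behaviour where a pairing exists. Two-sided throughout; no
multiple-testing correction (matching the original design); constant
features fall to the zero-variance convention (p = 1).

CFS merit uses **absolute Pearson/point-biserial correlations** for both
the feature-class and feature-feature terms. The canonical CFS evaluator
discretises features and uses symmetric uncertainty; for continuous
locomotor variables the correlation form is deterministic,
discretisation-free, and keeps the merit formula unchanged — a deliberate,
documented variant. Search is greedy-forward by default (best-first
available), tie-broken by feature name, and verified against exhaustive
subset enumeration on small candidate sets.

## Classification

C4.5-style recursive partitioning: candidate thresholds are midpoints
between consecutive distinct values whose class profiles differ
(boundary-point rule); the split maximises information gain ratio, with
ties broken by feature name then threshold so training is deterministic.
Prediction uses `value < threshold → left, ≥ → right`. Growth stops at
purity, `min_leaf` (default 2), `max_depth`, or no positive-gain split.
Pessimistic (upper-confidence, CF = 0.25) subtree-replacement pruning is
available but **off by default**: at the shallow tree sizes relevant here
it is immaterial, and on strongly overlapping class-conditional normals
the canonical estimate legitimately retains moderately deep trees, so the
tests assert structural properties (informative root variable, threshold
between class means, pruning monotonicity) rather than a fixed depth.

Cross-validation is seeded and stratified (falling back to plain shuffled
folds with a warning when a class has fewer rows than folds), pooling
confusion counts over folds; each class is designated positive in turn.
Undefined metrics (zero denominators) are reported as `None`, never as 0.

## Synthetic-track generator

The generator emulates the calibration-study conditions and is the ground
truth oracle the original study obtained from video:

* **Routine swimming** — tailbeat-locked (3 Hz) sinusoidal dynamic
  acceleration (lateral 2.0, surge 1.0, heave 3.47 m s⁻² amplitudes) and
  rotation (pitch 60, roll 110, yaw 160 deg s⁻¹ sharing the beat phase),
  plus 3 deg s⁻¹ heading drift. The heave amplitude is the calibration
  knob: at these defaults the windowed SD of MA sits at ≈ 2.5 m s⁻²
  (published routine value 2.47) and SD of MG at ≈ 62 deg s⁻¹
  (published 64.27).
* **Postural control** — free-running body-frame rotation sinusoids
  slowly tumble (rotations do not commute), which real fish actively
  prevent; a righting feedback (gain 1 s⁻¹) adds the small corrective
  pitch/roll rate *into the emitted gyro channel*, so attitude and gyro
  remain exactly consistent while tilt stays bounded (≈ 5° routine).
* **Fast-start bursts** — per-axis Gaussian-envelope oscillatory pulses
  whose signed peaks are drawn per event from normal distributions at the
  published class summaries (mean, SEM·√41): escapes are dominated by the
  lateral acceleration pulse (mean 89.05 m s⁻²) and yaw rotation
  (814.68 deg s⁻¹); feeding events are weaker (49.04 / 530.88) with a
  sustained ~0.5 s forward-acceleration plateau (the prey chase). Burst
  envelopes are narrow (τ = duration/8, i.e. tens of milliseconds of
  effective width — the timescale of fast-start acceleration transients)
  so within-window SDs stay well below the peaks, as in the published
  event summaries. Event normality is the minimal assumption consistent
  with mean-and-SEM summaries.
* **Consistency by construction** — measured acceleration = true dynamic
  acceleration + gravity through the true attitude + stored noise; the
  magnetometer reads a dipped (49°, mid-latitude) 0.46 Gauss earth field
  through the same attitude. The additivity audit (recording minus truth
  equals the stored noise realisation) is a test.

What the generator does **not** emulate: hydrodynamic coupling between
translation and rotation, tag-placement offsets from the centre of mass,
magnetic disturbance from infrastructure, sensor bias/temperature drift,
and the correlation structure *between* locomotor variables within an
event (the feature-level shortcut generator draws variables
independently). Passing tests therefore demonstrate that the pipeline
recovers what it is defined to recover under realistic amplitudes and
noise — not that field data will reach the same rates.

A second, feature-level generator (`sample_class_features`) draws feature
vectors directly from the per-class summaries without signal synthesis,
because classifier statistics over many seeds would be needlessly slow at
the signal level.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 100 injected events
(50/50) for detection precision/recall; 82 + 82 windowed-SD draws for
threshold learning (20 seeds in the tests); 41 + 41 events per class for
classification tables, with cross-validated accuracy averaged over 10
replicate tables in the acceptance script (a single 41+41 draw has
several points of CV-accuracy noise); 20 seeds for the variant-ordering
check, run on each variant's published selected variables — the
comparison design whose published rates (0.84 all-combined vs 0.66
gyro-only, inter-axial) the check reproduces in ordering. Because the
shortcut generator ignores inter-variable correlations, absolute CV
accuracies land a few points below the published ones (≈ 0.70 / 0.69 /
0.58); the ordering, not the absolute level, is the reproducible claim.

## Known limitations

* The filter gain, initialisation procedure and gyro bias handling of the
  original tank analysis are unpublished; all are config-exposed rather
  than hard-coded guesses.
* Events near recording boundaries are dropped (with a warning) rather
  than padded; the original boundary handling is unknown.
* The manual final-variable trim of the original workflow has no
  algorithmic definition; it is exposed as include/exclude lists in the
  pipeline config, and every intermediate is persisted so the step is
  reproducible.
* Supplementary raw example events exist for the original study but are
  not redistributable here; the corresponding spot-check (1-s escape
  event SD of MA clearing the 5.16 m s⁻² threshold) runs on a simulated
  escape event instead, labelled synthetic in the test.
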