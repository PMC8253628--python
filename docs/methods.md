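# Methods

This note documents the models, conventions and design choices behind
`footmotion`: what each stage computes, which constants matter and why they
have the values they do, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Signal model and preprocessing

A recording is a 100 Hz stream of accelerometer (g) and gyroscope (deg/s)
triples. A kick appears as a short (~0.1–0.4 s) burst on every channel over
a quiet baseline in which the accelerometer reads gravity. Preprocessing:

* **Moving average** (width 3, odd, configurable): centred window,
  replicate padding at the edges so output length equals input length.
  Chosen over zero padding because the signal's resting level is ~1 g, not
  0; zero padding would fabricate edge transients.
* **Peak detection** runs on the Euclidean norm of the filtered
  acceleration (both motions are acceleration bursts; the norm is
  orientation-invariant, so a tilted sensor does not move the operating
  point). Local maxima above `peak_threshold` (default **1.2 g**) are
  thinned greedily — taller peaks first, earlier index on exact ties — to a
  minimum separation (default 1.0 s). The threshold sits between the
  noise envelope of the gravity baseline (≈1.0 ± 0.1 g filtered) and the
  weakest admissible action pulse (≈1.4 g filtered), so detection is not a
  tuning knob for downstream accuracy.
* **Segmentation** cuts a `window_length` (default 1.0 s → W = 100
  samples) window centred on each peak. Peaks whose window would overrun
  the recording are dropped with a logged warning. The window covers the
  widest generated pulse (~0.4 s) plus baseline context for the attitude
  initialization.

## Attitude-angle model

Orientation is tracked per segment with unit quaternions
(scalar-first, p = (p₀, p₁, p₂, p₃)).

* **Initialization**: the segment's first accelerometer sample is assumed
  to measure gravity. It is normalized to unit magnitude first (raw
  components can exceed 1 g, which would leave arcsin undefined), then
  θ = arcsin(aₓ₀) (clamped), ψ = arctan(−a_y0/a_z0) (principal value,
  ±π/2 at a_z0 = 0), and φ = arctan(mag_y0 / mag_x0) where the two helper
  ratios are rational expressions in the components with denominators
  grouped as 1 − 2(·² + ·²) and 0/0 defined as 0. At rest with gravity on
  +z all three angles are zero. θ plays the role of a y-rotation (pitch),
  ψ an x-rotation (roll), φ a z-rotation (yaw); under that role assignment
  the half-angle product formula used to build the initial quaternion is
  exactly the standard Z-Y-X composition, which makes Euler round-trips
  well-posed.
* **Integration**: one first-order update q ← q + (Δt/2)·Ω(ω)·q per sample
  (Δt = 1/100 s, gyro converted deg/s → rad/s), renormalized after every
  step. Without renormalization the norm drifts and the extraction
  degrades; with it, the norm stays within 1e-12 per step (tested over
  10⁵ random steps). A first-order step at 100 Hz and rates ≤ ~1000 deg/s
  incurs < 1e-3 rad error over a 1 s window (tested against the
  closed-form single-axis rotation); a higher-order integrator is
  deliberately out of scope.
* **Extraction**: `standard` mode uses the conventional Z-Y-X extraction
  (atan2 for roll and yaw, clamped arcsin for pitch; clamping events are
  flagged in `AttitudeSeries.gimbal_flags`). `paper_literal` mode keeps
  the source formulation's printed row signs and arctangent ratios intact
  for auditability — two rate-matrix rows and two extraction numerators
  differ from the conventional kinematics (apparent sign/label typos in
  the source). In literal mode a vanishing denominator is treated as +0,
  so angles saturate at ±π/2 with the numerator's sign. `standard` is the
  default everywhere; which convention produced the study's published
  numbers cannot be determined, and all 34 features are computed from
  whichever trajectory is selected, so the feature-vector shape is
  unaffected.

## Features

34 statistics per segment, fixed column order (`features.FEATURE_NAMES`):
25 from the raw channels (RMS, variance, max/min, skewness, IQR, std of
specific axes) and 9 from the attitude trajectory (mean, RMS, std of
pitch, roll, yaw in radians). The set is exactly the named list — sibling
statistics that are not named (e.g. RMS of x-acceleration) are deliberately
absent. Estimator conventions, which the source never states, are fixed
as: population (1/n) moments; skewness m₃/m₂^{3/2} with the constant-input
case defined as 0 (guarded against floating-point residue in m₂);
linear-interpolation quantiles for the IQR. All kernels are contract-tested
against definition-level loops at 1e-9.

## PCA

Features mix units (g, deg/s, radians), so columns are standardized to
zero mean and unit population variance (zero-variance columns centred
only) before the SVD; unstandardized PCA would be dominated by the
deg/s-scaled columns. The retained dimension is the smallest r whose
cumulative explained variance reaches `pca_variance_kept` (default 0.95;
typically r ≈ 12–16 of 34 on default synthetic data). In the pipeline the
PCA is fitted on the training split only and applied to the test split.
PCA can be disabled (`use_pca=False`), in which case standardized features
go to the classifier directly.

## Classification and evaluation

The SVM grid is C ∈ {1, 500, 10³, 5·10³, 10⁴}, γ ∈ {10⁻⁵, 5·10⁻⁵, 10⁻⁴,
5·10⁻⁴, 10⁻³, 5·10⁻³}, kernel ∈ {linear, polynomial, RBF, sigmoid},
scanned exhaustively by mean stratified 3-fold CV accuracy; ties break
toward smaller C, then smaller γ, then the kernel order listed. γ is inert
for the linear kernel but still recorded with the winning configuration.
The underlying solver is libsvm (scikit-learn `SVC`) run at a tight
optimizer tolerance (1e-8) because the problems are small and the decision
function is contract-tested against an exact KKT-enumerated solution of
the dual quadratic program on tiny instances. Baselines: KNN with 4
neighbours; decision tree with `min_samples_split=3`, `max_depth=6`.

Splitting is stratified 80/20 (largest-remainder per-class rounding; e.g.
264 + 250 rows give 411 train / 103 test) and, like the CV fold
assignment, derives from the single `rng_seed`, so a run is a pure
function of (config, inputs) and repeated runs emit byte-identical
reports.

Reports carry the confusion matrix, per-class precision, recall and
F1 = 2PR/(P+R), and unweighted macro averages. Per-class precision is
additionally exposed under the alias `accuracy`, because assessment tables
in this literature sometimes print per-class precision under that name
(the printed F1 cells are consistent with 2PR/(P+R) of the printed
"accuracy" and recall columns, which the test suite verifies to three
decimals); `overall_accuracy` is the plain fraction correct.

The skill ("talent selection") task reuses the identical machinery with
elite/amateur labels, evaluated separately on the passing-only and
shooting-only segment subsets. `attitude_ablation_cv` quantifies the value
of the attitude model: it fixes the classifier at C = 1 with a linear
kernel (the configuration that wins on this data, so the comparison
isolates the feature sets) and returns the mean CV accuracy with and
without the 9 attitude columns.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, not soccer
biomechanics. Each action is a generalized-Gaussian envelope
exp(−|t/s|^p) on every channel (p = 2 is the Gaussian bell; s = σ√2 with
σ = duration/6), placed on a gravity baseline, with white noise. Default
design: 5 elite + 6 amateur subjects × 2 motions × 20 actions → 22
recordings, 440 labeled actions; peaks ≥ 2 s apart with uniform 0–0.3 s
extra spacing; 1 s of quiet padding at each end.

Class signatures and the reasoning behind the defaults:

* **Motion**: shooting is stronger than passing on both sensors
  (dominant-axis accelerometer amplitude 4.5 vs 2.0 g; secondary-axis
  gyro base 900 vs 500 deg/s). With the default action-to-action
  amplitude CVs this leaves the between-motion gap in mean peak
  acceleration at > 3× the within-motion spread, so motion recognition is
  solvable by construction — and a negative-control test confirms that
  inflating the amplitude CV to 0.8 collapses the separation.
* **Skill**: elite actions have larger and more repeatable ankle-rotation
  excursions. The dominant (y) gyro pulse is scaled so that its time
  integral equals the template's `attitude_swing` (passing 52°/34°,
  shooting 65°/42° for elite/amateur; per-action amplitude CV 0.08 vs
  0.18), and amateurs additionally address the ball with a tilted,
  variable resting foot posture (−12° ± 6° vs 0° ± 2° pitch tilt per
  recording) that enters the attitude trajectory through the
  initial-orientation estimate.
* **Attitude-driven structure**: per-action tempo jitter (lognormal
  σ = 0.5, clipped to [0.5, 2]) rescales the pulse width while the y-gyro
  amplitude is re-derived so the integral — hence the swing — is
  preserved, and per-action envelope-exponent jitter (lognormal σ = 0.25
  around 2, clipped to [1.2, 4]) varies the waveform shape. Together these
  prevent raw-channel moments from pinning down the pulse integral, so the
  skill signature is carried chiefly by the integrated attitude
  trajectory. This realizes, in generative form, the design premise that
  the angle-trajectory model adds information over raw-channel statistics;
  it is what makes the ablation contrast (below) meaningful rather than
  vacuous.
* **Noise**: 0.08 g and 40 deg/s white noise per channel. These model
  soft-tissue/impact artifact during kicks, which dwarfs the bare sensor
  noise of a consumer MEMS part; 40 deg/s leaves the integrated angle
  drift at a few degrees over the 1 s window.
* **Validity screen**: per-action amplitude factors are truncated below
  0.4, the generator's analogue of the study protocol in which actions
  outside a speed/precision range were discarded. Consequence: with noise
  disabled, every generated action clears the default detection threshold
  deterministically, which is what makes the 100 % noiseless-recovery
  check exact rather than probabilistic.

What the generator does **not** emulate: realistic leg-swing dynamics and
multi-phase kick kinematics (back-swing, impact ringing, follow-through),
soft-tissue artifact with realistic spectra, sensor bias/scale error and
axis misalignment, magnetometer-free heading drift over long recordings,
and between-session mounting variation. Passing tests therefore show that
the pipeline recovers the structure this generator encodes at realistic
amplitudes and noise levels — not that the published accuracies would be
reproduced on the embargoed study data.

## Problem sizes and determinism

Tests and the acceptance script use the full default design (22
recordings, 440 actions per seed) averaged over 20 seeds for the
end-to-end checks; unit and property tests use 1–4 subjects and 3–8
actions. Every source of randomness — generation, splitting, fold
assignment — flows from one integer seed, and reports serialize with
sorted keys, so identical runs are byte-identical.

## Known limitations

* Labels attach to detected segments by ordinal index within a recording.
  Because every recording contains a single (motion, skill) class this is
  robust to spurious or missed detections in practice, but interleaved
  multi-class recordings would need time-based label matching.
* First-order integration and the lack of drift correction limit segments
  to a few seconds; the design centres short windows on detected peaks
  precisely so this is immaterial.
* `paper_literal` mode reproduces the printed formulation faithfully,
  including its sign anomalies; its angle trajectories are not a rotation
  parameterization consistent with the standard mode and should be used
  for auditing only.
* The pitch arcsin clamp makes excursions beyond ±90° fold back; the
  generator keeps default swings below that region except in rare tails.
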