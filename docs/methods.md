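# Methods

## Problem and data model

The package implements simultaneous physical-activity recognition (PAR)
and steady-state energy-expenditure (EE) estimation from wearable inertial
(IMU) sensors, with ground-truth EE derived from indirect calorimetry. Two
device positions are modelled:

* **head** (eyeglass-mounted): tri-axial accelerometer and gyroscope, both
  at 128 Hz;
* **hip**: accelerometer at 90 Hz, gyroscope at 100 Hz.

A laboratory session consists of six structured activities (seated
computer work, sweeping, stationary cycling, treadmill walking, treadmill
running, one-vs-one basketball), each annotated with start/stop times and a
weight-bearing flag, while breath-by-breath oxygen uptake is exported as
30-s epochs (mL·min⁻¹).

## Signal processing

1. **Resampling.** The hip accelerometer is up-sampled 90 → 100 Hz with a
   rational-rate polyphase resampler (`scipy.signal.resample_poly`). We use
   a Kaiser window with β = 14 and linear edge extension, which keeps the
   passband ripple below 10⁻⁶ so a constant signal survives resampling
   essentially unchanged; edge transients are suppressed to the same level.
2. **Clipping.** All gyroscope channels are clipped to ±400 deg/s to remove
   extreme outliers. No de-noising filters are applied.
3. **8-bit rescale.** Each channel is mapped to integers in [0, 255] by the
   min-max rescale x′ = ⌊NM + (x − x_min)/(x_max − x_min) · NMa⌋ with
   NM = 0, NMa = 255, following the printed form literally (with NM = 0 it
   coincides with the conventional NM + (…)·(NMa − NM)). A floor removes
   the fractional part; the result is clamped to [0, 255] as a guard
   against floating-point overshoot. A constant channel maps entirely to NM
   with a warning. The extent over which x_min/x_max are computed is
   configurable (`window`, `segment`, `recording`); the default is **per
   channel per 10-s window**, making each image self-contained and robust
   to slow drift. Note that window-scope rescaling deliberately discards
   absolute amplitude; classification must then rely on temporal structure.
4. **Grouping.** Rescaled channels are grouped into three sensor
   combinations — acc_gyr (6 columns, order ax, ay, az, gx, gy, gz), acc
   (3), gyr (3). The column order is a package convention recorded in the
   dataset manifest.
5. **Windowing.** 10-s windows are cut inside each activity segment.
   *Sequential* windows start at the segment start and advance by a step
   equal to the window length (non-overlapping) — the step is configurable.
   *Random* windows draw their start uniformly from the feasible range and
   serve as augmentation; per segment their default count equals the
   sequential count. Trailing partial windows are discarded, never padded.
   Test sets contain only sequential windows. Each window becomes an 8-bit
   grayscale image of height = samples (1280 head, 1000 hip) and width =
   channel count, stored losslessly as PNG plus a provenance manifest.

## Ground truth

Relative VO₂ divides the epoch's absolute VO₂ by body mass; for
weight-bearing activities 2 kg are added for the worn calorimeter unit and
harness (the stationary-cycling segment is marked non-weight-bearing in
the default manifest; the flag is data, not code). METs = relative VO₂ /
3.5 mL·kg⁻¹·min⁻¹. The steady-state EE of an activity discards the final
30-s epoch and averages the four epochs immediately preceding it; an epoch
belongs to an activity iff its full span lies inside the segment. Windows
fully inside a segment inherit (class, steady-state METs); windows
overlapping a boundary (transitions) are excluded and counted. Class
indices are assigned alphabetically over the label set.

## Model

The multitask CNN operates on the grayscale window image (scaled to [0, 1])
plus the participant's body mass (standardised by training-set mean/sd) and
produces an M-way activity posterior and a positive MET estimate.

* **Shared blocks** (default 4, kernel counts 16/32/64/128): convolution
  along the time axis only (kernel 9 × 1; channels are heterogeneous
  physical axes, so no cross-channel mixing in the convolution), ReLU,
  average pooling (4 × 1), batch normalisation over the feature axis,
  dropout 0.2. The paper-facing block order (conv → pool → norm → dropout)
  is kept; the ReLU after the convolution is a package choice — a
  convolutional stack without a nonlinearity cannot compose features.
  Kernel counts, sizes and dense widths were tuned by grid search in the
  original study but not reported; the defaults here are the package's own.
* **Head-1 (PAR)**: the final block's features are averaged along time
  (global average pooling) and flattened over channel × feature, then pass
  dense layers (default 128, 64) to a softmax. Time pooling makes the head
  invariant to where in the window a movement pattern occurs; without it
  the head can memorise phase positions specific to training participants,
  which we observed to destroy held-out-subject generalisation.
* **Head-2 (EE)**: the same time-averaged features of a configurable block
  subset (default blocks 1 + 2; any non-empty subset of blocks is valid,
  enabling the block-routing sweep), concatenated with standardised body
  mass, through dense layers to a single output mapped by softplus
  (METs > 0). The output bias starts at 3.0 so initial predictions sit in
  the physiologic mid-range. Pooling here also keeps the head's input
  low-dimensional: feeding the raw flattened maps (~10⁴ features) into a
  narrow dense layer made Adam's first coherent steps drive every ReLU
  unit negative, permanently killing the head.

Losses: categorical cross-entropy (log clamped at 10⁻¹²) for PAR, mean
squared error for EE, both averaged (not summed) over the batch so the
learning rate is batch-size invariant. The combined loss is
w₁·L_PAR + w₂·L_EE with w₁ + w₂ = 1.

## Training regimes

* **Two-step progressive**: step 1 trains shared blocks + Head-1 under
  cross-entropy; step 2 freezes every shared and Head-1 parameter —
  including batch-norm running statistics, by running the blocks in
  inference mode — and trains Head-2 alone under MSE. The freeze is exact
  (bit-identical parameters), which the tests assert.
* **One-step hard parameter sharing**: all parameters trained jointly under
  the combined loss; the history logs both components per epoch. With
  w₁ = 1 the joint regime reproduces step 1 of progressive training
  bit-for-bit (Head-2 consumes no randomness and zero-weighted heads are
  excluded from the update), which is tested.

Optimisation is Adam (the optimiser is unstated in the source study; Adam
is the package's choice) with the study's stated defaults: batch 100,
initial learning rate 2·10⁻⁵ halved every 10 epochs, at most 200 epochs,
early stopping with patience 25 on the validation loss of whatever is
being optimised (step-specific in two-step, combined in one-step), with
best-weights restore. The w₁ grid search runs one-step training per value
(default 0.1…0.9) and picks, among the top-half accuracies, the value with
the lowest MAPE.

## Evaluation

Leave-one-subject-out: one fold per participant, the held-out participant's
sequential windows forming the test set. The remaining participants'
windows are split 3:1 into train:validation, stratified by (participant,
activity) — a by-participant 3:1 split is impossible with five remaining
participants, so the split is window-level. Fold hygiene (no test-window
provenance in train/validation, test sequential-only) is asserted at fold
construction. Reported per fold: window-level accuracy and macro-averaged
precision/recall/F1 (the averaging scheme is unstated in the source study;
macro is the package's choice), EE MSE (METs²) and MAPE (fraction) over
per-window predictions, plus a per-activity table of predicted vs. actual
steady-state METs, where the steady-state prediction is the mean predicted
EE over the activity's windows. Cross-fold summaries are unweighted means.

## Synthetic study generator

Because the original 6-participant dataset is not deposited, the package
ships a generator that emulates all four raw inputs with known ground
truth. Each activity has a signal profile: a dominant movement cadence
(0 Hz computer, 1.0 Hz sweeping, 1.2 Hz cycling, 1.8 Hz walking, 2.8 Hz
running, broadband basketball), 1–3 harmonics with device-specific
amplitudes (hip gait amplitudes exceed head amplitudes; cycling is
leg-dominant and weak at the head), gravity offsets, Gaussian channel
noise, and occasional gyro spikes beyond ±400 deg/s to exercise clipping.
Broadband activities use 0.5–8 Hz band-passed noise. VO₂ epochs follow an
exponential approach (default time constant 30 s) from the previous
activity's level to base METs × a per-participant multiplier
(sd 0.08), times 3.5 × (mass + 2·weight_bearing), with 2% multiplicative
noise; the implied steady-state MET value is recorded in an oracle file.
Defaults: 6 participants, masses uniform in 55–100 kg, six 6-min bouts
with 20-s gaps, written as the same CSV dialects the ingest reads,
deterministic given the seed.

What the generator does **not** emulate: posture changes, sensor drift and
bias, within-activity pace variation, inter-participant differences in
movement signature (only the metabolic multiplier varies), or free-living
behaviour. Passing the recovery benchmark therefore demonstrates that the
pipeline and model are implemented coherently end to end — not that the
model would reach comparable accuracy on real human data.

## Reference benchmark (reduced scale)

The repository's recovery benchmark runs the full pipeline at desk scale:
6 participants, 150-s bouts, hip device (exercising the 90 → 100 Hz
resample), acc_gyr combo, 5 random windows per segment, and a 3-block
(8/16/32-kernel) model with 32-wide heads trained with batch 50, learning
rate 10⁻³ halved every 15 epochs, at most 25 epochs per step, patience 8.
Three blocks are the minimum at which the pooled receptive field (~1.7 s at
100 Hz) spans a full cycle of the slowest cadences, which the classifier
needs to separate activities by frequency. The benchmark thresholds —
held-out PAR accuracy ≥ 0.90 and EE MAPE ≤ 0.20 — are repository constants
established from the reference run of this benchmark. The frozen-backbone
contract is checked on a 204-window miniature dataset with a 2-block
(8/16) model.

## Numerical notes and limitations

* All network arithmetic is float32; training is deterministic given the
  seed and a fixed thread configuration.
* Batch-norm running statistics use momentum 0.1 and ε = 10⁻⁵; early
  stopping restores best weights but, as is conventional, running
  statistics remain those of the last trained epoch (except across the
  two-step freeze, where they are part of the frozen state).
* `resample_to_rate` preserves duration to within one output sample;
  output length follows the resampler's ceiling convention.
* Random window starts are drawn in continuous time and snapped to the
  sample grid; random windows may overlap sequential ones (they are drawn
  independently).
* MAPE is reported as a fraction (multiply by 100 for percent) and is
  undefined when any actual value is zero; the error message lists the
  offending indices.
* Annotation timestamps are assumed to be on each recording's own
  timeline; clock synchronisation between devices is out of scope.
* Proprietary device formats (.gt3x, SD-card binaries, calorimeter
  exports) are not parsed; inputs are the documented CSV dialects.
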