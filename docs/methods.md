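# Methods

## Problem

Manual wheelchair users load their shoulders heavily and repeatedly during
everyday activities, and sustained overload is a suspected driver of
shoulder pain and pathology.  The gold standard for quantifying
shoulder-joint reaction force (SJRF) — musculoskeletal modeling driven by
optical motion capture and instrumented-wheel kinetics — is confined to the
laboratory.  This package implements an alternative: learn a mapping from
wearable-sensor signals (five IMUs on the arm, trunk and wheelchair; two
surface EMG channels) to the continuous 3D SJRF, so that shoulder load can
be estimated outside the lab.  The pipeline covers signal preprocessing,
cross-validation design, sequence-regression models, evaluation metrics and
shoulder-load-profile comparison, exercised end to end on a synthetic
cohort whose structure mirrors the wheelchair-activity study design it
emulates.

## Synthetic cohort

Real recordings of this kind are not publicly deposited, so the package
ships a generator that produces raw multi-rate streams with a known ground
truth.  Per participant it emits 8 activities split into 19 subtrials:
weight-relief lifts (2 × 10 s), propulsion in a restricted space
(3 × 15 s), treadmill propulsion at three conditions (slow / fast /
inclined, 2 × 15 s each), ramp ascent and descent (2 × 8 s), manual
material handling (3 × 12 s) and desk work (3 × 10 s).  Durations for the
activities without a protocol-stated length (restricted propulsion, ramp,
material handling) were chosen so a 10-participant cohort lands near
~6,000 25 Hz samples per participant, matching the scale of the emulated
study design.  The default cohort is 10 participants with 7 pseudo-randomly
excluded subtrials → 183 valid subtrials.

Each subtrial is driven by four latent states: arm elevation angle θ(t)
(rad), normalized push force p(t) ∈ [0, 1], and two muscle activations
a₁(t), a₂(t) ∈ [0, 1].  Activity templates are smooth parametric signals:
sinusoids at the participant's propulsion cadence for cyclic activities (an
amplitude modulation is added for restricted-space propulsion), a smoothed
boxcar hold for the weight-relief lift (with staggered latent timing and a
2.2 Hz postural tremor during the hold), Gaussian pulse trains for material
handling, and a low-amplitude random Fourier series for desk work.

The SJRF target is a documented nonlinear mapping of the latents
(coefficients in `SJRF_COEFFS`, newtons):

```
Fx = 250·m·max(p̃ − 0.4, 0)² + 30·ã₁ + 5
Fy = 120·m·ã₂·sin θ + 20·θ
Fz = 40·m + 60·m·ã₁ + 25·sin θ
```

where m is the participant's body-mass scale and p̃, ã₁, ã₂ are first-order
lags (τ = 0.8 s) of p, a₁, a₂, emulating activation-to-force dynamics
(muscle force build-up and decay).  Two properties are deliberate:

* the lag states make the mapping **non-instantaneous** — a per-sample
  feedforward model cannot reconstruct them from the current sample, while
  a recurrent model can integrate the history, and
* the rectified-**quadratic** push term is only substantially exercised
  during sustained pushes (weight-relief holds), so a model that never saw
  that activity must extrapolate a curved branch it has no data for.

Sensor channels are simple biomechanics-flavoured functions of the latents:
accelerometers see the gravity projection of segment orientation plus
angular-acceleration terms and a per-participant mounting bias, gyroscopes
see θ̇ (in °/s), the wheelchair sensors see push-force reaction and a
cadence-locked wheel-speed ripple, and raw EMG is a 30–400 Hz band-limited
carrier amplitude-modulated by the activation and a per-muscle gain.
Per-participant heterogeneity (body-mass scale, cadence, EMG gains,
mounting bias) is drawn from documented distributions whose spread scales
linearly with a single `heterogeneity` parameter (default 0.3; 0 makes all
participants identical).  Every stream except the reference (upper-arm IMU)
and the force series carries a hidden clock offset drawn uniformly from
±0.5 s, and every stream starts with a high-amplitude triphasic fiducial
burst 0.9 s before the activity, giving the synchronization stage a
recoverable ground truth.  Default sensor noise is 0.2 m/s² on
accelerometers (×5 in °/s on gyroscopes).

What the generator does **not** emulate: soft-tissue artifact, sensor
drift and bias instability, electrode lift-off, crosstalk between muscles,
nonstationary cadence, and — most importantly — the true musculoskeletal
relation between movement and joint force.  Passing tests therefore show
that the pipeline recovers a known nonlinear, temporally lagged mapping
from realistic multi-rate, mis-synchronized, noisy streams; they do not
certify accuracy on human data.

## Preprocessing

All filters are 4th-order Butterworth, applied zero-phase
(forward–backward, reflect padding of 3 × order samples), the biomechanics
convention; the effective magnitude response is the squared single-pass
response, so a sine at the cutoff emerges with amplitude 0.5.  IMU channels
are low-passed at 10 Hz; EMG is processed exactly in the order: high-pass
20 Hz → offset correction (subtract the trial mean) → full-wave
rectification → low-pass 3 Hz → division by the submaximal reference →
clipped at 0; the force series is low-passed at 4 Hz.  The EMG reference is
the **mean** (not peak) of the pre-normalization envelope over a window in
the static-posture recording (held submaximal contraction).  Streams are
synchronized by maximizing normalized cross-correlation of a burst-dominated
trace against the upper-arm IMU over ±2 s; a correlation peak below 0.2
yields a warning and a zero offset.  All streams are then linearly
interpolated onto one shared 25 Hz grid over the protocol-known activity
window (prior low-pass filtering keeps everything below the 12.5 Hz Nyquist
of the target rate, so linear interpolation is alias-safe).

## Datasets and cross-validation

Two sensor setups: *complete* (5 IMUs × 6 channels + 2 EMG = 32 columns)
and *sparse* (upper-arm IMU + two wheelchair IMUs + 2 EMG = 20 columns),
with a fixed, documented column order.  Cross-validation designs:

* **LOTO** (leave-one-trial-out, subject-specific): per participant, each
  valid subtrial is the test set once; the remaining subtrials split into
  train and validation.
* **LOSO** (leave-one-subject-out, generalizable): one fold per
  participant; the held-out participant is the test set.

The validation hold-out for early stopping is 15 % of the training
subtrials (at least one), drawn seeded at subtrial granularity in a
round-robin over activities so it spans them, while never taking an
activity's last training subtrial.  Standardization removes the per-column
mean and scales to unit variance (population SD), fitted on training
subtrials only; validation and test data are transformed with the train
statistics, and a constant column is an error.

## Models and training

Both models map the standardized input sequence to the standardized 3D
force sequence and are implemented in numpy with hand-written
backpropagation (verified against finite differences in the test suite):

* **biLSTM**: 3 bidirectional LSTM layers, 128 units per direction
  (concatenated output width 256), each followed by dropout p = 0.37 and
  ReLU, then a linear map to 3.  "Units" are per direction; the
  recurrent → dropout → ReLU block order is our reading of the
  architecture.  One bias vector per gate block.
* **feedforward ("linear") model**: time-distributed dense layers
  250 → 100 (ReLU after each) → 3; for a 20-wide input this is exactly
  30,653 parameters.

Training: masked MSE on standardized targets over batches of 8 whole
padded sequences, Adam at learning rate 1e-3 with global-norm gradient
clipping at 1.0 (the optimizer, batch construction and clipping are our
choices; whole-sequence batches preserve the temporal context bidirectional
recurrence exploits).  At most 200 epochs; training stops once the
validation loss has not improved for 6 consecutive epochs, and the
parameters of the best validation epoch are restored.  Experiments repeat
training for 10 iterations differing only in seed.  Everything is
deterministic given (seed, data, config).

## Evaluation

The headline signal is Ftot = ‖(Fx, Fy, Fz)‖ per sample.  Agreement between
predicted and ground-truth Ftot is scored with Pearson's r (PCC) and the
relative RMSE (rRMSE = 100 · RMSE / range of ground-truth Ftot).  Subtrial
predictions are concatenated back to whole activities; activity-level
records score each (participant, activity) per iteration and average over
iterations, participant-level records concatenate all of a participant's
activities within an iteration ("complete iteration") and score once.
Activities left incomplete by exclusions are dropped from activity-level
aggregation with a log entry, not imputed.

Shoulder-load profiles are histograms of Ftot with 25 N bins anchored at
0 N (half-open bins, final bin closed), built on edges shared between the
two series being compared.  Profile similarity is the Swain–Ballard
intersection I(y, ŷ) = Σ min(yᵢ, ŷᵢ) / Σ yᵢ with y the ground-truth
counts; since both series share a time base, I ∈ [0, 1] and I(y, y) = 1.

## Stepwise experiment

Model selection fixes one factor per step, carrying winners forward:
(1) LOTO vs LOSO with the complete setup and biLSTM; (2) complete vs sparse
with the winning strategy; (3) biLSTM vs feedforward with the winning
strategy and setup.  The winner is the configuration with the higher mean
participant-level PCC, ties broken by lower mean rRMSE (the selection rule
is our formalization; step reports include the full metric tables so any
other rule can be applied post hoc).

## Scaled-down study sizes

The repository's automated checks run three studies at sizes chosen to be
informative on a single desk-class CPU; the sizes are design choices
documented here and in the code:

* **Parameter recovery**: 3 participants, duration scale 0.35 (~110
  samples per subtrial), sensor noise 0.02, LOTO + sparse + biLSTM, one
  iteration; model scaled to 32 units/direction with a 50-epoch cap.
* **Architecture comparison**: one participant per seed, three seeds,
  every third LOTO fold, default noise 0.2; batches of 2 whole sequences —
  single-participant folds hold only ~16 sequences, and smaller batches
  give both architectures enough optimizer steps per epoch.
* **Unseen-activity probe**: 3 participants with one forced orphaned
  weight-relief subtrial, three seeds, heterogeneity 0.15, noise 0.05; the
  orphan LOTO fold, every third non-orphan fold, and the LOSO fold of the
  orphan participant, again at batch size 2.

The full-size protocol (10 participants, 10 iterations, 128-unit biLSTM,
all folds) is available behind `shoulderload run-experiment --full`.

## Numerical choices and degenerate inputs

Pearson correlation of a constant series is undefined and returned as NaN
with a warning; rRMSE with a zero ground-truth range is an error.  EMG
envelopes are clipped at 0 after the 3 Hz low-pass (filter ringing can
undershoot).  Filter application requires the signal to exceed the padding
length; cutoffs at or above Nyquist raise a configuration error naming the
channel.  Latent-state derivatives are central finite differences at
h = 1/512 s; the lag states are computed by exponential smoothing on an
internal 100 Hz grid.  Fold construction, trait sampling, trial synthesis,
dropout and batch shuffling all draw from explicit seed hierarchies
(`numpy.random.default_rng` with composite seed keys), so equal seeds give
byte-identical cohorts and training runs.

## Known limitations

The generator's activity dynamics are caricatures; no claim of
biomechanical fidelity is made.  The sparse-vs-complete comparison is
less interesting on synthetic data than in reality because the synthetic
thorax and lower-arm channels carry genuinely redundant information by
construction.  The LSTM implementation is CPU-bound numpy; it is fast
enough for the scaled studies but not intended for large cohorts.
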