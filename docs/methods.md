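# Methods

This note documents the models, procedures and numerical choices behind
`intentsense`, and what its synthetic cohorts can and cannot show about
real recordings.

## Pipeline overview

Raw input per trial: five 9-channel IMU streams at 50 Hz (3-axis
magnetometer, gyroscope, accelerometer) with a per-sample 3×3
orientation matrix, one mono 44.1 kHz waveform, a per-trial activity
label, and a per-subject static calibration segment.

1. **Calibration correction.** Each IMU stream's mean orientation
   during the calibration pose — the element-wise mean of its rotation
   matrices projected onto SO(3) by SVD (determinant forced to +1) — is
   inverted and applied to all of that stream's 3-axis modalities and
   composed with its orientation channel. A rank-deficient mean raises
   a diagnostic error.
2. **Heading randomisation.** One random rotation per trial, identical
   for all five streams, removes the subject's starting direction so
   classifiers cannot exploit it. Default is yaw-only (about the global
   vertical): a full random 3D rotation would also corrupt the gravity
   reference; it is available via `PipelineConfig.full_3d_heading`.
3. **Audio features.** The waveform is cut into contiguous 882-sample
   frames (one per IMU sample; trailing surplus discarded, no padding).
   Per frame: symmetric 882-point Hamming window, power spectrum
   (|rfft|²/882), 26 triangular mel filters spanning 0–22 050 Hz on the
   HTK mel scale (2595·log10(1+f/700)), natural log floored at 1e-10
   (so silence maps to a finite constant vector), orthonormal DCT-II,
   first 18 coefficients kept — coefficient 1 is the energy (0th)
   coefficient. This dialect is fixed and documented; bit-compatibility
   with any particular audio toolbox is not claimed. 18 coefficients
   match the 18 features each IMU contributes (9 channels + 9 rotation
   entries), so no sensor is favoured a priori: 6 × 18 = 108 features.
4. **Standardisation.** Per-sensor, per-feature z-scoring with
   statistics from the training subjects of each cross-validation fold
   only; constant features fall back to unit scale. Added because the
   centroid backend and small-network training are scale-sensitive.
5. **Segmentation.** 500 ms windows (25 samples) advancing by a common
   hop. 250 ms overlap at 50 Hz is 12.5 samples, which is not an
   integer; the hop is floored to 12 samples (240 ms advance, 260 ms
   overlap), a documented deviation from the nominal figure. Window k
   ends at 0.5 + (k−1)·0.24 s; the default 20.5 s horizon gives 84
   evaluation steps. All six sensors share identical boundaries — the
   alignment assumption fusion relies on.

## Classifiers

Two backends implement the same contract (probability over the 3
classes per window, argmax vote with lowest-index tie-break):

* `lstm` — a bidirectional LSTM authored in numpy (`lstm.py`): 15
  hidden units per direction (the bidirectional reading of "15 hidden
  units"), final forward/backward hidden states concatenated into a
  fully connected softmax layer; trained 50 epochs with Adam at
  learning rate 0.001, mini-batch 512, seeded Glorot initialisation
  with +1 forget-gate bias, full BPTT. Reproducible under a fixed seed
  on a fixed platform; gradients are verified against finite
  differences in the test suite.
* `lightweight` — deterministic nearest-class-centroid on window-mean
  features. It exists so the fusion mathematics can be tested exactly
  and evaluations run at desk scale; it is the default backend for the
  shipped experiments.

Per-sensor classifiers see 18 features; the non-modular reference sees
all 108. Both see identical window boundaries and labels. For the
weighted fusion methods each LOSO training set is randomly halved into
a Classifier-Learning and a Confusion-Matrix-Learning subject set
(sizes differing by at most one); majority voting needs no confusion
matrices and may train on the full set.

**Confusion matrices.** For each (sensor, step), the 3×3 counts of
(true, voted) over all Confusion-Matrix-Learning windows pooled across
subjects and trials, plus a Laplace pseudo-count (alpha = 1, so no cell
is zero and the Bayes rule never degenerates), row-normalised into the
likelihood table L[e, v].

## Fusion

The posterior for intent e given all votes up to step t is the product
of per-vote likelihoods normalised over the three classes (the printed
two-event Bayes form with the complement event expanded as the
prior-weighted mean of the other classes reduces to exactly this under
a uniform prior). Computation is in the log domain by default;
linear-domain agreement within 1e-9 is asserted in tests. Hard argmax
votes are fused — that is what confusion-matrix weighting operationally
means; expected-likelihood fusion of soft probabilities is available
behind `FusionConfig.soft_votes` but is not the default path.
Sensor-order invariance, normalisation, and equivalence with a
brute-force joint enumeration are tested properties, as is modularity:
any sensor subset fuses without retraining.

The naive bound `P_B = 1 − Π(1 − P(S_i))` evaluates the union of
per-sensor successes under independence. P(S_i) is the mean diagonal of
sensor i's likelihood table at the terminal step (a per-step bound
curve from per-step diagonals is also reported). The bound is
approximate — measured accuracy occasionally exceeds it; violations are
counted and reported, never hidden.

**Spearman monotonicity.** Ranks of accuracy and time (average ranks on
ties) are correlated by the product-moment formula, which equals the
printed d² formula exactly when no ties exist; ties are likely where
curves saturate near 1. A constant curve returns r_s = 0 with a
warning. The implementation is cross-checked against an independent
rank-correlation oracle on random permutations.

**Evaluation.** Leave-one-subject-out over the cohort; a trial is
correct at step t iff the fused decided class at step t equals the
label (not any-step-so-far). Accuracy pools trials across folds; 95%
CIs are a seeded percentile bootstrap over subjects (1000 resamples by
default). Group comparison reports per-group curves and the earliest
step reaching a threshold accuracy (default 0.99995, i.e. 100.00% to
two decimal places). Four independent seed streams (cohort, split,
training, bootstrap) allow stages to be varied in isolation.

## The synthetic cohort generator

The generator is a first-class, tested component that emulates the
statistical structure the pipeline assumes; it makes no attempt at
biomechanical realism.

* **Cohort.** Default 15 patients / 19 controls; per-subject latents:
  motion scale U(0.8, 1.2), variability (noise multiplier) U(0.8, 1.2)
  for controls and U(1.15, 1.6) for patients, tremor amplitude
  U(0.5, 1.5) m/s² for patients and 0 for controls, a per-subject
  mounting misalignment rotation (angle ≤ 0.35 rad), and per-stream
  posture deviations whose spread grows with variability.
* **Class signal.** Each (activity, stream) pair has a posture rotation
  with a characteristic axis and peak angle; the posture is partially
  expressed at inception (anticipatory) and keeps developing until
  ~14 s, so separability — and hence accuracy — rises over the whole
  evaluation horizon. Because every trial receives a random yaw, the
  class tables separate in yaw-invariant structure: the *magnitude* of
  tilt away from vertical per stream, not its horizontal direction.
  Accelerometer (gravity through the orientation), magnetometer (fixed
  global field), gyroscope (angular velocity) and the orientation
  channel all carry it. Class-specific limb-oscillation frequencies add
  a secondary cue. Head-stream angles are smallest, making it a weak
  IMU, and audio is weakest overall (a design target mirroring the
  reported per-sensor spread).
* **Audio.** Band-limited (300–3000 Hz) Gaussian babble stands in for
  conversation — never speech, consistent with the method's exclusion
  of speech analysis — plus a faint sustained class tone and a
  class-specific event train (key-turn-like 1.2 kHz bursts, button
  clicks from a fixed pseudo-noise template, a 260 Hz toaster-like
  buzz), aligned to the IMU clock at exactly 882 audio samples per IMU
  sample (no resampling path).
* **Patients.** An amplitude-modulated 4–6 Hz tremor enters as a direct
  accelerometer/gyro term and as an orientation wobble over an
  orthonormal axis triad with decorrelated phases, so on average every
  channel of every modality gains variance; on a single trial the
  finite-sample covariance between tremor and posture motion can exceed
  the small added variance of a weakly coupled magnetometer channel,
  which is why the variance property is stated (and tested) as an
  expectation over a session's trials. Patient difficulty flows mainly
  through `variability`, which scales channel noise (sub-linearly) and
  trial-level posture jitter; under cumulative fusion, persistent
  subject-level deviation hurts far more than window-level noise, which
  largely dithers out over time.
* **Null and determinism contracts.** Every class-dependent term scales
  with `contrast` (contrast 0 is an exact null: identically distributed
  classes, chance-level accuracy). Every trial-level stochastic term
  scales with `noise` (noise 0 with zero tremor makes repeats
  bit-identical). Identical seeds give bit-identical cohorts.

**Calibration of defaults.** The free parameters (posture tables,
stream gains, noise levels, audio levels) were calibrated once against
the generator's own stated design targets: single-sensor lightweight
accuracy in the ~0.7–0.9 band with audio weakest, approximately
monotone fused curves, and non-trivial fusion gains. They are study
*conditions*, not tuning knobs.

## What passing tests do and do not show

The synthetic cohorts exercise every pipeline contract — alignment,
leakage, determinism, fusion mathematics, monotone qualitative
behaviour — but real recordings differ in ways the generator does not
model: genuine limb kinematics and within-trial activity phases,
speech, sensor dropout, clock drift, magnetic disturbances, and the
overfitting pressure that makes small high-dimensional deep networks
underperform. Two consequences observed here: the centroid backend
gains little from doubling the training set, so the weighted Bayes
methods outperform majority voting on synthetic cohorts (the reported
study found the reverse for its LSTM, attributing majority voting's
advantage to its doubled training data); and at the full 34-subject
scale the 108-feature combined centroid does not overfit, so the
modular advantage over the combined method is smaller than a
high-capacity learner would show. Reported accuracies on synthetic
cohorts say nothing quantitative about accuracy on clinical data.

## Numerical choices and degenerate inputs

* Mean rotation: SVD projection; singular values below 1e-12 raise.
* Tie-breaks: argmax at equal probability decides the lowest class
  index, everywhere.
* Log-domain fusion avoids underflow across 6 sensors × 84 steps.
* MFCC log floor 1e-10; all-zero frames give finite output.
* Standardiser: unit fallback scale for constant features.
* Zero CM-learning windows at a (sensor, step) give pure pseudo-count
  tables with a warning; a horizon beyond the shortest trial truncates
  with a warning; degenerate LOSO folds are skipped and counted.
* Problem sizes in the shipped experiments (6–12 subjects in tests, 34
  in the acceptance script; 21 s trials; hop 12) are the package's
  desk-scale defaults; all are configurable.

## Known limitations

* The hop quantisation (12 not 12.5 samples) shifts late-step end times
  by up to 0.4 s relative to a true 250 ms overlap.
* Whether the original system fused soft probabilities or hard votes,
  and whether its "two weighted methods" are the per-step and
  step-pooled variants implemented here, is an interpretation (both
  variants ship).
* P(S_i) in the naive bound is terminal-step mean-diagonal accuracy;
  other readings (per-step, balanced) are possible.
* The numpy LSTM is sequential Python over 25 time steps; it is
  practical for the shipped cohort sizes but not optimised for large
  studies.
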