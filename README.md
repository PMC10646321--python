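# intentsense

Modular, time-segmented, multi-modal **intent sensing**: classifying
which activity of daily living a person intends to perform — here
opening a door, buttoning a cardigan, or making toast — continuously
from the moment the activity begins, using five body-worn IMUs and a
room microphone. The target use case is assistive technology for people
with mobility-limiting conditions such as Parkinson's disease, where
recognising intent early lets a device help complete the task.

## The method

Each sensor stream is cut into overlapping 500 ms windows (250 ms
nominal overlap). A per-sensor classifier (bidirectional LSTM, or a
deterministic nearest-centroid "lightweight" backend) assigns each
window a class vote, so at time step *t* there is one vote per sensor
per elapsed step. Fusion combines all votes up to *t*:

* **Confusion-matrix-weighted Bayes rule.** For intent *E* and observed
  votes *V*,

      P(E | V) = P(V | E) P(E) / [ P(V | E) P(E) + P(V | E') P(E') ]

  with a uniform prior, P(E) = 1/3 and P(E') = 2/3. Assuming
  independence between sensors (and steps), P(V | E) is the product of
  per-vote likelihoods L_{s,t}[e, v] = P(vote v | true e) — the
  row-stochastic confusion matrices of each sensor at each time step,
  estimated on a held-out half of the training subjects (the
  *Confusion-Matrix-Learning* set) and Laplace-smoothed. Variants:
  per-(sensor, step) tables (`bayes_sensor_time`) or step-pooled
  per-sensor tables (`bayes_sensor_only`).

* **Majority voting**, giving every (sensor, step) vote equal weight. It
  needs no confusion matrices, so its classifiers may train on the full
  training set (`majority_full`); `majority_half` discards half to make
  it comparable to the weighted methods.

* A **naive upper bound** on fused accuracy from per-sensor accuracies
  under independence: `P_B = 1 - prod_i (1 - P(S_i))`.

* **Monotonicity** of each accuracy-vs-time curve is quantified by
  Spearman's rank correlation
  `r_s = 1 - 6 Σ (RP_i - RT_i)² / (n(n² - 1))`.

Evaluation is leave-one-subject-out: every subject's trials are held
out once, classifiers and confusion matrices are learned on the rest,
and per-step accuracy is pooled over held-out trials, with percentile
bootstrap CIs over subjects. A *modular* system fuses the six
single-sensor classifiers; the *combined* (non-modular) reference is a
single classifier over all 108 features.

Because no public recording of the original cohort exists, the package
ships a seeded synthetic cohort generator (`intentsense.synthetic`)
that emulates the study's structure: patients and controls, 3
activities × 3 repeats, five 9-channel 50 Hz IMU streams with
per-sample orientation matrices and a calibration pose, 44.1 kHz audio
with conversational babble, class-specific sound events, per-subject
mounting misalignment, and a 4–6 Hz tremor plus extra variability for
the patient group.

## Worked example

```python
from intentsense import GeneratorConfig, PipelineConfig
from intentsense.model import IntentSensingModel

generator = GeneratorConfig(n_patients=3, n_controls=3)
pipeline = PipelineConfig(cohort_seed=7, split_seed=8, training_seed=9,
                          bootstrap_seed=10, n_bootstrap=200)
model = IntentSensingModel.from_synthetic(generator, seed=7, pipeline=pipeline)
results = model.fit()
print(results.summary())
```

prints

```
Intent-sensing LOSO evaluation
================================================================
subjects: 6   trials: 54   steps: 84 (0.5-20.42 s)
backend: lightweight   hop: 12 samples

method            scope       acc@0.5s   max acc  terminal  Spearman
--------------------------------------------------------------------
bayes_sensor_only combined      0.6481    0.8704    0.8704     0.986
bayes_sensor_only network       0.6111    0.9444    0.9444     0.957
bayes_sensor_time combined      0.6111    0.9259    0.9259     0.961
bayes_sensor_time network       0.6667    0.9444    0.9259     0.906
majority_full     combined      0.7222    0.8889    0.8704     0.937
majority_full     network       0.6481    0.7963    0.7778     0.760
majority_half     combined      0.6481    0.8519    0.8519     0.987
majority_half     network       0.4815    0.7963    0.7963     0.983

individual sensors (majority voting over time):
  imu_ul     acc@0.5s 0.6667   terminal 0.7778
  ...
  audio      acc@0.5s 0.3519   terminal 0.6667

naive upper bound (terminal): 0.997031 from per-sensor accuracies ...
```

Reading it: at 0.5 s after activity inception the fused modular Bayes
system (`bayes_sensor_time`/`network`) already classifies 67% of
held-out trials correctly; accuracy rises approximately monotonically
(Spearman 0.91) to 0.93–0.94 by the 20.5 s horizon, above every
individual sensor, with audio the weakest sensor. The naive bound is
the independence-based ceiling implied by the per-sensor accuracies.
`results.curve("bayes_sensor_time")`, `results.to_frame()` and
`results.plot_accuracy()` expose the full curves.

The same pipeline is scriptable from the shell:

```bash
intentsense generate --out cohort/ --seed 1 --n-subjects 6
intentsense run --data cohort/ --seed 1 --methods bayes_sensor_time,majority_full --out results/
```

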