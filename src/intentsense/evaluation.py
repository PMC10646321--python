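"""Leave-one-subject-out evaluation: accuracy-vs-time curves and statistics.

For every held-out subject the harness trains the requested classifiers
on the remaining subjects, learns confusion matrices on the
Confusion-Matrix-Learning half, fuses the held-out trials' votes with
each requested method, and scores correctness at every evaluation step.
Curves pool trials across folds; 95% confidence intervals come from a
seeded percentile bootstrap over subjects.

A trial counts as correct at step t iff the fused decided class at step
t equals the trial's true activity (not any-step-so-far correctness).

The monotonicity of each curve is quantified by Spearman's rank
correlation between accuracy and time,

    r_s = 1 - 6 * sum_i (RP_i - RT_i)^2 / (n (n^2 - 1)),

computed as the product-moment correlation of average ranks (which
equals the printed formula exactly when no ties are present; ties are
likely near accuracy 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .classifiers import (
    COMBINED,
    ConfusionMatrixSet,
    learn_confusion_matrices,
    make_splits,
    predict_fold_votes,
    train_classifiers_for_fold,
)
from .config import ACTIVITIES, ALL_SENSORS, PipelineConfig
from .fusion import FusionConfig, NaiveBound, fuse_trial, naive_upper_bound
from .segmentation import WindowedDataset, WindowedTrial, window_end_times

__all__ = [
    "AccuracyCurve",
    "MonotonicityResult",
    "NaiveBoundCurve",
    "LosoOutcome",
    "run_loso",
    "spearman_monotonicity",
    "bootstrap_ci",
    "compare_groups",
    "naive_gap",
    "threshold_crossing_step",
]

_LABEL_INDEX = {a: i for i, a in enumerate(ACTIVITIES)}


@dataclass
class AccuracyCurve:
    """Fraction of test trials classified correctly at each time step."""

    method: str
    sensor_scope: str  # "network" (modular), "combined", or a single sensor id
    steps: np.ndarray
    end_times_s: np.ndarray
    accuracy: np.ndarray
    ci95: np.ndarray | None = None  # (2, n_steps) lower/upper
    group: str = "all"
    n_trials: int = 0

    def __post_init__(self) -> None:
        if np.any(self.accuracy < -1e-12) or np.any(self.accuracy > 1 + 1e-12):
            raise ValueError("accuracies must lie in [0, 1]")
        if np.any(np.diff(self.steps) <= 0):
            raise ValueError("steps must be strictly increasing")


@dataclass(frozen=True)
class MonotonicityResult:
    """Spearman rank correlation of an accuracy-vs-time curve."""

    rs: float
    n: int
    accuracy_ranks: np.ndarray
    time_ranks: np.ndarray
    tied: bool


def spearman_monotonicity(
    accuracies: np.ndarray | AccuracyCurve, times: np.ndarray | None = None
) -> MonotonicityResult:
    """Spearman's r_s between accuracy and time, with average-rank ties.

    When ties exist the product-moment correlation of ranks is used (the
    textbook d-squared formula assumes none); a constant accuracy curve
    returns r_s = 0 with a warning.
    """
    if isinstance(accuracies, AccuracyCurve):
        times = accuracies.end_times_s
        accuracies = accuracies.accuracy
    acc = np.asarray(accuracies, dtype=float)
    t = np.arange(1, len(acc) + 1, dtype=float) if times is None else np.asarray(times, dtype=float)
    if len(acc) < 3:
        raise ValueError("need at least 3 steps for a rank correlation")
    rp = rankdata(acc, method="average")
    rt = rankdata(t, method="average")
    tied = len(np.unique(rp)) < len(rp) or len(np.unique(rt)) < len(rt)
    sp, st = rp.std(), rt.std()
    if sp < 1e-15 or st < 1e-15:
        warnings.warn("constant ranks: Spearman r_s set to 0 by convention", stacklevel=2)
        return MonotonicityResult(0.0, len(acc), rp, rt, tied)
    rs = float(np.mean((rp - rp.mean()) * (rt - rt.mean())) / (sp * st))
    return MonotonicityResult(rs, len(acc), rp, rt, tied)


def bootstrap_ci(
    correct: np.ndarray,
    subject_ids: list[str],
    n_resamples: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Percentile bootstrap over subjects of per-step accuracy.

    ``correct`` is (n_trials, n_steps) boolean; trials are resampled at
    the subject level (all of a subject's trials enter together).
    Returns (2, n_steps): the central 95% interval.
    """
    subject_ids = np.asarray(subject_ids)
    unique = np.unique(subject_ids)
    groups = {s: np.flatnonzero(subject_ids == s) for s in unique}
    rng = np.random.default_rng(seed)
    stats = np.empty((n_resamples, correct.shape[1]))
    for b in range(n_resamples):
        chosen = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([groups[s] for s in chosen])
        stats[b] = correct[idx].mean(axis=0)
    return np.percentile(stats, [2.5, 97.5], axis=0)


@dataclass
class NaiveBoundCurve:
    """Per-step naive upper bound and the per-sensor accuracies behind it."""

    steps: np.ndarray
    p_bound: np.ndarray  # (n_steps,)
    terminal: NaiveBound  # Eq.-2 bound at the terminal step


@dataclass
class LosoOutcome:
    """Everything run_loso measures, before presentation."""

    steps: np.ndarray
    end_times_s: np.ndarray
    curves: dict[tuple[str, str], AccuracyCurve]
    sensor_curves: dict[str, AccuracyCurve]
    correctness: dict[tuple[str, str], np.ndarray]  # (n_trials, n_steps) bool
    trial_subjects: list[str]
    trial_groups: list[str]
    naive_bound: NaiveBoundCurve
    n_excluded_folds: int = 0


def _fuse_and_score(
    votes: dict[str, np.ndarray],
    trials: list[WindowedTrial],
    cms: ConfusionMatrixSet | None,
    method: str,
    steps: list[int],
    pipeline: PipelineConfig,
    scope_sensors: list[str],
) -> np.ndarray:
    """Correctness (n_trials, n_steps) for one method over one fold's tests."""
    fcfg = FusionConfig(
        method=method, log_domain=pipeline.log_domain, soft_votes=pipeline.soft_votes
    )
    out = np.zeros((len(trials), len(steps)), dtype=bool)
    for i, trial in enumerate(trials):
        per_sensor = {s: votes[s][i] for s in scope_sensors}
        posteriors = fuse_trial(per_sensor, cms, fcfg, steps=steps)
        truth = _LABEL_INDEX[trial.label]
        out[i] = np.array([p.decided_class == truth for p in posteriors])
    return out


def run_loso(
    dataset: WindowedDataset,
    pipeline: PipelineConfig | None = None,
    methods: list[str] | None = None,
    backend: str | None = None,
    progress: bool = False,
) -> LosoOutcome:
    """Leave-one-subject-out evaluation of every requested fusion method.

    Returns pooled accuracy curves for the modular network and the
    combined (non-modular) classifier under each method, plus individual
    per-sensor curves (majority voting over time with full-data
    classifiers) and the naive upper-bound curve.
    """
    pipeline = pipeline or PipelineConfig()
    methods = list(methods or pipeline.methods)
    backend = backend or pipeline.backend
    subject_ids = dataset.subject_ids
    splits = make_splits(subject_ids, pipeline.split_seed)
    n_steps_h = len(
        [
            k
            for k in range(1, dataset.n_steps + 1)
            if window_end_times(dataset.n_steps, dataset.hop_samples)[k - 1]
            <= pipeline.horizon_s + 1e-9
        ]
    )
    steps = list(range(1, n_steps_h + 1))
    end_times = window_end_times(n_steps_h, dataset.hop_samples)

    need_half = any(
        m in methods for m in ("bayes_sensor_time", "bayes_sensor_only", "majority_half")
    )
    sensor_scopes = list(ALL_SENSORS)
    all_scopes = sensor_scopes + [COMBINED]

    keys = [(m, sc) for m in methods for sc in ("network", COMBINED)]
    correctness: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in keys}
    sensor_correct: dict[str, list[np.ndarray]] = {s: [] for s in sensor_scopes}
    trial_subjects: list[str] = []
    trial_groups: list[str] = []
    fold_sensor_acc: list[dict[str, float]] = []
    fold_step_acc: list[np.ndarray] = []  # (n_steps, n_sensors) mean diagonals
    n_excluded = 0

    for f, split in enumerate(splits):
        test_trials = dataset.for_subjects([split.test_subject])
        if not test_trials:
            n_excluded += 1
            warnings.warn(f"no trials for subject {split.test_subject}; fold skipped")
            continue
        cl_trials = dataset.for_subjects(split.classifier_learning)
        cm_trials = dataset.for_subjects(split.cm_learning)
        full_trials = cl_trials + cm_trials

        # z-scoring statistics come from the training subjects only; the
        # held-out subject is transformed with those statistics
        mu, sd = _fit_standardizer(full_trials)
        cl_s = [_standardize(t, mu, sd) for t in cl_trials]
        cm_s = [_standardize(t, mu, sd) for t in cm_trials]
        test_s = [_standardize(t, mu, sd) for t in test_trials]
        full_s = cl_s + cm_s

        cms = None
        votes_test_half = None
        if need_half:
            clf_half = train_classifiers_for_fold(
                cl_s, n_steps_h, backend, pipeline, pipeline.training_seed + f, all_scopes
            )
            votes_cm = predict_fold_votes(clf_half, cm_s, n_steps_h)
            labels_cm = np.array([_LABEL_INDEX[t.label] for t in cm_s])
            cms = learn_confusion_matrices(
                votes_cm, labels_cm, n_steps_h, pipeline.smoothing_alpha
            )
            votes_test_half = predict_fold_votes(clf_half, test_s, n_steps_h)
            fold_sensor_acc.append(
                {s: cms.sensor_accuracy(s) for s in sensor_scopes}
            )
            fold_step_acc.append(
                np.stack(
                    [
                        np.array(
                            [
                                np.mean(np.diag(cms.likelihood(s, k)))
                                for s in sensor_scopes
                            ]
                        )
                        for k in steps
                    ]
                )
            )
        # full-data classifiers drive majority_full and the per-sensor curves
        clf_full = train_classifiers_for_fold(
            full_s, n_steps_h, backend, pipeline, pipeline.training_seed + f, all_scopes
        )
        votes_test_full = predict_fold_votes(clf_full, test_s, n_steps_h)

        for method in methods:
            if method == "majority_full":
                v = votes_test_full
                c = None
            elif method == "majority_half":
                v = votes_test_half
                c = None
            else:
                v = votes_test_half
                c = cms
            correctness[(method, "network")].append(
                _fuse_and_score(v, test_s, c, method, steps, pipeline, sensor_scopes)
            )
            correctness[(method, COMBINED)].append(
                _fuse_and_score(v, test_s, c, method, steps, pipeline, [COMBINED])
            )
        for s in sensor_scopes:
            sensor_correct[s].append(
                _fuse_and_score(
                    votes_test_full, test_s, None, "majority_full", steps, pipeline, [s]
                )
            )
        trial_subjects.extend(t.subject_id for t in test_trials)
        trial_groups.extend(t.group for t in test_trials)
        if progress:
            print(f"fold {f + 1}/{len(splits)}: held out {split.test_subject}")

    curves: dict[tuple[str, str], AccuracyCurve] = {}
    correct_arrays: dict[tuple[str, str], np.ndarray] = {}
    steps_arr = np.asarray(steps)
    for key, blocks in correctness.items():
        arr = np.concatenate(blocks, axis=0)
        correct_arrays[key] = arr
        ci = bootstrap_ci(
            arr, trial_subjects, pipeline.n_bootstrap, pipeline.bootstrap_seed
        )
        curves[key] = AccuracyCurve(
            method=key[0],
            sensor_scope=key[1],
            steps=steps_arr,
            end_times_s=end_times,
            accuracy=arr.mean(axis=0),
            ci95=ci,
            n_trials=arr.shape[0],
        )
    sensor_curves = {}
    for s, blocks in sensor_correct.items():
        arr = np.concatenate(blocks, axis=0)
        sensor_curves[s] = AccuracyCurve(
            method="majority_full",
            sensor_scope=s,
            steps=steps_arr,
            end_times_s=end_times,
            accuracy=arr.mean(axis=0),
            n_trials=arr.shape[0],
        )

    if fold_sensor_acc:
        mean_acc = {
            s: float(np.mean([d[s] for d in fold_sensor_acc])) for s in sensor_scopes
        }
        step_acc = np.mean(np.stack(fold_step_acc), axis=0)  # (n_steps, n_sensors)
        bound_steps = 1.0 - np.prod(1.0 - step_acc, axis=1)
        naive = NaiveBoundCurve(
            steps=steps_arr, p_bound=bound_steps, terminal=naive_upper_bound(mean_acc)
        )
    else:
        # no weighted method requested: bound from per-sensor test accuracy
        acc = {s: float(sensor_curves[s].accuracy[-1]) for s in sensor_scopes}
        per_step = np.stack([sensor_curves[s].accuracy for s in sensor_scopes], axis=1)
        naive = NaiveBoundCurve(
            steps=steps_arr,
            p_bound=1.0 - np.prod(1.0 - per_step, axis=1),
            terminal=naive_upper_bound(acc),
        )

    return LosoOutcome(
        steps=steps_arr,
        end_times_s=end_times,
        curves=curves,
        sensor_curves=sensor_curves,
        correctness=correct_arrays,
        trial_subjects=trial_subjects,
        trial_groups=trial_groups,
        naive_bound=naive,
        n_excluded_folds=n_excluded,
    )


def _fit_standardizer(trials: list[WindowedTrial]):
    stacked = np.concatenate([t.features for t in trials], axis=0)  # (sum_T, 6, 18)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _standardize(trial: WindowedTrial, mu: np.ndarray, sd: np.ndarray) -> WindowedTrial:
    return WindowedTrial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        group=trial.group,
        label=trial.label,
        features=(trial.features - mu) / sd,
        hop_samples=trial.hop_samples,
        n_steps=trial.n_steps,
    )


def compare_groups(
    outcome: LosoOutcome,
    key: tuple[str, str],
    pipeline: PipelineConfig | None = None,
) -> dict[str, dict]:
    """Per-group (patient/control) curves with bootstrap CIs and the
    earliest step at which accuracy first reaches the report threshold."""
    pipeline = pipeline or PipelineConfig()
    correct = outcome.correctness[key]
    groups = np.asarray(outcome.trial_groups)
    subjects = np.asarray(outcome.trial_subjects)
    present = [g for g in ("patient", "control") if np.any(groups == g)]
    if len(present) < 2:
        warnings.warn("single-group cohort: reporting available group only")
    report = {}
    for g in present:
        mask = groups == g
        arr = correct[mask]
        ci = bootstrap_ci(
            arr, list(subjects[mask]), pipeline.n_bootstrap, pipeline.bootstrap_seed
        )
        acc = arr.mean(axis=0)
        report[g] = {
            "curve": AccuracyCurve(
                method=key[0],
                sensor_scope=key[1],
                steps=outcome.steps,
                end_times_s=outcome.end_times_s,
                accuracy=acc,
                ci95=ci,
                group=g,
                n_trials=arr.shape[0],
            ),
            "threshold_step": threshold_crossing_step(
                acc, outcome.steps, pipeline.threshold_accuracy
            ),
        }
    return report


def threshold_crossing_step(
    accuracy: np.ndarray, steps: np.ndarray, threshold: float
) -> int | None:
    """Earliest step index whose accuracy reaches the threshold (None if never)."""
    hits = np.flatnonzero(np.asarray(accuracy) >= threshold)
    return int(np.asarray(steps)[hits[0]]) if hits.size else None


def naive_gap(curve: AccuracyCurve, bound: NaiveBoundCurve) -> dict:
    """Per-step (bound - accuracy) with summary; negative gaps (accuracy
    above the approximate bound) are reported, never hidden."""
    if len(curve.accuracy) != len(bound.p_bound):
        raise ValueError("curve and bound cover different steps")
    gap = bound.p_bound - curve.accuracy
    return {
        "per_step": gap,
        "max_gap": float(gap.max()),
        "terminal_gap": float(gap[-1]),
        "violations": int(np.sum(gap < -1e-12)),
    }
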