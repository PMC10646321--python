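"""Per-sensor sequence classifiers, LOSO splits and confusion matrices.

The modular path trains one classifier per sensor (18 input features);
the non-modular path trains a single classifier on all six sensors
concatenated (108 features).  For the confusion-matrix-weighted fusion
methods, each leave-one-subject-out training set is randomly halved into
a Classifier Learning set and a Confusion Matrix Learning set; the
latter provides per-sensor, per-time-step 3x3 confusion counts whose
Laplace-smoothed row-stochastic form is the Bayes likelihood table.

Two backends exist: ``lstm`` (the bidirectional LSTM of
:mod:`intentsense.lstm`) and ``lightweight``, a fully deterministic
nearest-class-centroid rule on window-mean features used for exact
oracle tests and fast evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ACTIVITIES, ALL_SENSORS, PipelineConfig
from .lstm import BiLSTMClassifier
from .segmentation import WindowedTrial

__all__ = [
    "TrainingSplit",
    "make_splits",
    "SensorClassifier",
    "CentroidClassifier",
    "LSTMSensorClassifier",
    "train_sensor_classifier",
    "predict_window",
    "ConfusionMatrixSet",
    "learn_confusion_matrices",
    "COMBINED",
]

COMBINED = "combined"
N_CLASSES = len(ACTIVITIES)
_LABEL_INDEX = {a: i for i, a in enumerate(ACTIVITIES)}


@dataclass(frozen=True)
class TrainingSplit:
    """One LOSO fold: held-out subject + the two training half-sets."""

    test_subject: str
    classifier_learning: tuple[str, ...]
    cm_learning: tuple[str, ...]
    split_seed: int

    @property
    def training_subjects(self) -> tuple[str, ...]:
        """Union of both learning sets (the majority-voting full-data path)."""
        return self.classifier_learning + self.cm_learning


def make_splits(subject_ids: list[str], seed: int) -> list[TrainingSplit]:
    """One leave-one-subject-out split per subject.

    The remaining subjects are randomly halved into the Classifier
    Learning and Confusion Matrix Learning sets (sizes differ by at most
    one), deterministically under ``seed``.
    """
    subject_ids = list(subject_ids)
    if len(subject_ids) < 3:
        raise ValueError("need at least 3 subjects for LOSO with a halved training set")
    rng = np.random.default_rng(seed)
    splits = []
    for test_subject in subject_ids:
        rest = [s for s in subject_ids if s != test_subject]
        perm = list(rng.permutation(rest))
        half = (len(perm) + 1) // 2
        splits.append(
            TrainingSplit(
                test_subject=test_subject,
                classifier_learning=tuple(perm[:half]),
                cm_learning=tuple(perm[half:]),
                split_seed=seed,
            )
        )
    return splits


# --------------------------------------------------------------------------
# backends


class SensorClassifier:
    """Base: predicts a probability vector over the 3 classes per window."""

    def __init__(self, sensor_id: str, input_width: int):
        self.sensor_id = sensor_id
        self.input_width = input_width

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:  # (N, 25, F) -> (N, 3)
        raise NotImplementedError

    def predict_votes(self, windows: np.ndarray) -> np.ndarray:
        """Argmax votes with ties broken toward the lowest class index."""
        return np.argmax(self.predict_proba(windows), axis=1)


class CentroidClassifier(SensorClassifier):
    """Deterministic nearest-class-centroid rule on window-mean features.

    The probability vector is one-hot on the nearest centroid (ties go to
    the lowest class index), so a window equal to its own class centroid
    is classified with probability 1.
    """

    def __init__(self, sensor_id: str, input_width: int):
        super().__init__(sensor_id, input_width)
        self.centroids_: np.ndarray | None = None  # (3, F)

    def fit(self, windows: np.ndarray, labels: np.ndarray) -> "CentroidClassifier":
        x = self._window_means(windows)
        labels = np.asarray(labels, dtype=int)
        present = np.unique(labels)
        if len(present) < N_CLASSES:
            missing = sorted(set(range(N_CLASSES)) - set(present.tolist()))
            raise ValueError(
                f"degenerate training set for sensor {self.sensor_id!r}: "
                f"no windows for class index(es) {missing}"
            )
        self.centroids_ = np.stack(
            [x[labels == c].mean(axis=0) for c in range(N_CLASSES)]
        )
        return self

    def _window_means(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 2:  # already window means
            x = windows
        else:
            x = windows.mean(axis=1)
        if x.shape[-1] != self.input_width:
            raise ValueError(
                f"window width {x.shape[-1]} does not match classifier "
                f"input width {self.input_width}"
            )
        return x

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        if self.centroids_ is None:
            raise RuntimeError("classifier is not fitted")
        x = self._window_means(np.atleast_2d(windows))
        d2 = ((x[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        probs = np.zeros((x.shape[0], N_CLASSES))
        probs[np.arange(x.shape[0]), np.argmin(d2, axis=1)] = 1.0
        return probs


class LSTMSensorClassifier(SensorClassifier):
    """Bidirectional LSTM backend mirroring the stated architecture:
    15 hidden units per direction, 50 epochs, learning rate 0.001,
    mini-batch 512, softmax over 3 classes, seeded initialisation
    (reproducible under a fixed seed on a fixed platform)."""

    def __init__(self, sensor_id: str, input_width: int, config: PipelineConfig, seed: int):
        super().__init__(sensor_id, input_width)
        self.net = BiLSTMClassifier(
            n_features=input_width,
            n_classes=N_CLASSES,
            hidden_units=config.hidden_units,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=seed,
        )

    def fit(self, windows: np.ndarray, labels: np.ndarray) -> "LSTMSensorClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < N_CLASSES:
            raise ValueError(
                f"degenerate training set for sensor {self.sensor_id!r}: "
                "at least one window per class is required"
            )
        self.net.fit(np.asarray(windows, dtype=float), labels)
        return self

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 2:
            windows = windows[None, ...]
        return self.net.predict_proba(windows)


def train_sensor_classifier(
    windows: np.ndarray,
    labels: np.ndarray,
    sensor_id: str,
    backend: str = "lightweight",
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> SensorClassifier:
    """Train one per-sensor (or combined) window classifier.

    ``windows`` is (N, 25, F) — F is 18 for a single sensor, 108 for the
    combined non-modular classifier.  Labels are activity names or class
    indices.
    """
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = np.array([_LABEL_INDEX[l] for l in labels])
    width = windows.shape[-1]
    if backend == "lightweight":
        clf: SensorClassifier = CentroidClassifier(sensor_id, width)
    elif backend == "lstm":
        clf = LSTMSensorClassifier(sensor_id, width, config or PipelineConfig(backend="lstm"), seed)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return clf.fit(windows, labels)


def predict_window(classifier: SensorClassifier, window: np.ndarray):
    """Probability vector and argmax vote (ties -> lowest class index)."""
    probs = classifier.predict_proba(np.asarray(window, dtype=float)[None, ...])[0]
    return probs, int(np.argmax(probs))


# --------------------------------------------------------------------------
# confusion matrices


@dataclass
class ConfusionMatrixSet:
    """Per-sensor, per-time-step 3x3 confusion counts and likelihoods.

    ``counts[sensor]`` is (n_steps, 3, 3) with entry [t, e, v] the number
    of Confusion-Matrix-Learning windows of true class e voted v at step
    t+1.  ``likelihood`` returns the row-stochastic table
    L[e, v] = P(vote v | true e) after adding ``smoothing_alpha``
    pseudo-counts to every cell (so no entry is ever zero and the Bayes
    rule never degenerates).
    """

    counts: dict[str, np.ndarray]
    smoothing_alpha: float = 1.0

    @classmethod
    def from_likelihoods(
        cls, likelihoods: dict[str, np.ndarray], smoothing_alpha: float = 0.0
    ) -> "ConfusionMatrixSet":
        """Build directly from row-stochastic tables, (n_steps, 3, 3) per
        sensor (or (3, 3), broadcast to one step). Zero alpha keeps them."""
        counts = {}
        for sensor, like in likelihoods.items():
            arr = np.asarray(like, dtype=float)
            if arr.ndim == 2:
                arr = arr[None, ...]
            counts[sensor] = arr
        return cls(counts=counts, smoothing_alpha=smoothing_alpha)

    @property
    def n_steps(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    @property
    def sensors(self) -> list[str]:
        return list(self.counts)

    def _normalize(self, counts: np.ndarray) -> np.ndarray:
        smoothed = counts + self.smoothing_alpha
        return smoothed / smoothed.sum(axis=-1, keepdims=True)

    def likelihood(self, sensor: str, step_index: int) -> np.ndarray:
        """Smoothed L for one (sensor, step), step_index 1-based."""
        return self._normalize(self.counts[sensor][step_index - 1])

    def likelihoods(self, sensor: str) -> np.ndarray:
        """All steps at once, (n_steps, 3, 3)."""
        return self._normalize(self.counts[sensor])

    def pooled_likelihood(self, sensor: str) -> np.ndarray:
        """Step-pooled L_s (counts summed over steps, then smoothed)."""
        return self._normalize(self.counts[sensor].sum(axis=0))

    def sensor_accuracy(self, sensor: str, step_index: int | None = None) -> float:
        """Mean-diagonal accuracy of a sensor's likelihood table.

        Defaults to the terminal step (the P(S_i) fed to the naive
        upper-bound model).
        """
        step = self.n_steps if step_index is None else step_index
        return float(np.mean(np.diag(self.likelihood(sensor, step))))

    def to_frame(self):
        """Tidy export: one row per (sensor, step, true, voted) count."""
        import pandas as pd

        rows = []
        for sensor, counts in self.counts.items():
            like = self._normalize(counts)
            for t in range(counts.shape[0]):
                for e in range(N_CLASSES):
                    for v in range(N_CLASSES):
                        rows.append(
                            {
                                "sensor": sensor,
                                "step": t + 1,
                                "true_class": ACTIVITIES[e],
                                "voted_class": ACTIVITIES[v],
                                "count": int(counts[t, e, v]),
                                "likelihood": like[t, e, v],
                            }
                        )
        return pd.DataFrame(rows)


def learn_confusion_matrices(
    votes: dict[str, np.ndarray],
    labels: np.ndarray,
    n_steps: int,
    smoothing_alpha: float = 1.0,
) -> ConfusionMatrixSet:
    """Count (true class, voted class) per sensor and step.

    ``votes[sensor]`` is (n_trials, n_steps) of voted class indices over
    the Confusion-Matrix-Learning trials; ``labels`` is (n_trials,) of
    true class indices.  Windows are pooled across all CM-learning
    subjects and trials at each step.
    """
    labels = np.asarray(labels, dtype=int)
    counts: dict[str, np.ndarray] = {}
    for sensor, v in votes.items():
        v = np.asarray(v, dtype=int)
        if v.shape != (len(labels), n_steps):
            raise ValueError(
                f"votes for {sensor!r} must be (n_trials, {n_steps}), got {v.shape}"
            )
        c = np.zeros((n_steps, N_CLASSES, N_CLASSES))
        for t in range(n_steps):
            np.add.at(c[t], (labels, v[:, t]), 1.0)
        if len(labels) == 0:
            warnings.warn(
                f"no CM-learning windows for sensor {sensor!r}; "
                "likelihoods are pure pseudo-counts",
                stacklevel=2,
            )
        counts[sensor] = c
    return ConfusionMatrixSet(counts=counts, smoothing_alpha=smoothing_alpha)


# --------------------------------------------------------------------------
# batch helpers over windowed trials


def train_classifiers_for_fold(
    trials: list[WindowedTrial],
    n_steps: int,
    backend: str,
    config: PipelineConfig,
    seed: int,
    scopes: list[str],
) -> dict[str, SensorClassifier]:
    """Train classifiers for the requested scopes on the given trials.

    Scopes are sensor ids (modular, 18 features each) and/or
    ``"combined"`` (non-modular, 108 features).  All scopes see identical
    window boundaries and labels.
    """
    labels = np.repeat(
        [_LABEL_INDEX[t.label] for t in trials], n_steps
    )
    classifiers: dict[str, SensorClassifier] = {}
    if backend == "lightweight":
        # centroid backend consumes window means directly
        means = np.concatenate([t.window_means[:n_steps] for t in trials])  # (N, 6, 18)
        for scope in scopes:
            if scope == COMBINED:
                x = means.reshape(means.shape[0], -1)
            else:
                x = means[:, ALL_SENSORS.index(scope), :]
            classifiers[scope] = train_sensor_classifier(
                x, labels, scope, backend, config, seed
            )
    else:
        for scope in scopes:
            blocks = []
            for t in trials:
                if scope == COMBINED:
                    full = np.stack(
                        [
                            np.concatenate(
                                [t.window(s, k) for s in range(len(ALL_SENSORS))],
                                axis=1,
                            )
                            for k in range(1, n_steps + 1)
                        ]
                    )
                    blocks.append(full)
                else:
                    s = ALL_SENSORS.index(scope)
                    blocks.append(
                        np.stack([t.window(s, k) for k in range(1, n_steps + 1)])
                    )
            x = np.concatenate(blocks)
            classifiers[scope] = train_sensor_classifier(
                x, labels, scope, backend, config, seed
            )
    return classifiers


def predict_fold_votes(
    classifiers: dict[str, SensorClassifier],
    trials: list[WindowedTrial],
    n_steps: int,
) -> dict[str, np.ndarray]:
    """Votes per scope for each trial and step: (n_trials, n_steps)."""
    votes: dict[str, np.ndarray] = {}
    for scope, clf in classifiers.items():
        per_trial = []
        for t in trials:
            if isinstance(clf, CentroidClassifier):
                means = t.window_means[:n_steps]
                if scope == COMBINED:
                    x = means.reshape(means.shape[0], -1)
                else:
                    x = means[:, ALL_SENSORS.index(scope), :]
                per_trial.append(clf.predict_votes(x))
            else:
                if scope == COMBINED:
                    w = np.stack(
                        [
                            np.concatenate(
                                [t.window(s, k) for s in range(len(ALL_SENSORS))],
                                axis=1,
                            )
                            for k in range(1, n_steps + 1)
                        ]
                    )
                else:
                    s = ALL_SENSORS.index(scope)
                    w = np.stack([t.window(s, k) for k in range(1, n_steps + 1)])
                per_trial.append(clf.predict_votes(w))
        votes[scope] = np.stack(per_trial)
    return votes
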