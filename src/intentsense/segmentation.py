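"""Time segmentation: overlapping 500 ms windows indexed by time step.

Each trial's six feature streams are cut into 25-sample (500 ms at
50 Hz) windows advancing by a common hop; every window is a separate
labelled sample indexed by its time step, and all six sensors of a trial
share identical window boundaries (the fusion alignment requirement).

The nominal 250 ms overlap is 12.5 samples at 50 Hz; the default hop is
floored to 12 samples (240 ms advance, 260 ms overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ALL_SENSORS, FS_IMU
from .preprocessing import TrialFeatures

__all__ = [
    "TimeWindow",
    "WindowedTrial",
    "WindowedDataset",
    "segment_trial",
    "segment_cohort",
    "evaluation_steps",
    "window_count",
    "window_end_times",
]

WINDOW_SAMPLES = 25  # 500 ms at 50 Hz


@dataclass(frozen=True)
class TimeWindow:
    """One labelled window of one sensor at one time step (1-based)."""

    trial_id: str
    subject_id: str
    sensor_id: str
    step_index: int
    samples: np.ndarray  # (25, 18)
    label: str
    window_end_time_s: float


def window_count(n_samples: int, hop_samples: int, window_samples: int = WINDOW_SAMPLES) -> int:
    """Number of full windows in a stream of ``n_samples`` samples."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // hop_samples + 1


def window_end_times(n_steps: int, hop_samples: int, window_samples: int = WINDOW_SAMPLES) -> np.ndarray:
    """End time (s) of each step: step k ends at 0.5 + (k-1)*hop/50."""
    k = np.arange(1, n_steps + 1)
    return (window_samples + (k - 1) * hop_samples) / FS_IMU


@dataclass
class WindowedTrial:
    """All windows of one trial, stored densely.

    ``features`` keeps the full streams, (T, 6, 18); windows are views
    ``features[start : start + 25]``.  ``window_means`` (lazily cached)
    gives the per-window feature means used by the lightweight backend,
    shape (n_steps, 6, 18).
    """

    trial_id: str
    subject_id: str
    group: str
    label: str
    features: np.ndarray  # (T, n_sensors, 18)
    hop_samples: int
    n_steps: int
    _means: np.ndarray | None = field(default=None, repr=False)

    @property
    def end_times_s(self) -> np.ndarray:
        return window_end_times(self.n_steps, self.hop_samples)

    def window(self, sensor_index: int, step_index: int) -> np.ndarray:
        start = (step_index - 1) * self.hop_samples
        return self.features[start : start + WINDOW_SAMPLES, sensor_index, :]

    @property
    def window_means(self) -> np.ndarray:
        if self._means is None:
            starts = np.arange(self.n_steps) * self.hop_samples
            idx = starts[:, None] + np.arange(WINDOW_SAMPLES)[None, :]
            # (n_steps, 25, n_sensors, 18) -> mean over the 25 samples
            self._means = self.features[idx].mean(axis=1)
        return self._means

    def iter_windows(self, sensor_id: str) -> list[TimeWindow]:
        s = ALL_SENSORS.index(sensor_id)
        ends = self.end_times_s
        return [
            TimeWindow(
                trial_id=self.trial_id,
                subject_id=self.subject_id,
                sensor_id=sensor_id,
                step_index=k,
                samples=self.window(s, k),
                label=self.label,
                window_end_time_s=float(ends[k - 1]),
            )
            for k in range(1, self.n_steps + 1)
        ]


def segment_trial(trial: TrialFeatures, hop_samples: int = 12) -> WindowedTrial:
    """Cut one trial's six streams into aligned overlapping windows.

    Windows start at sample 1 (activity inception) and advance by
    ``hop_samples``; a window needing samples beyond the stream end is
    not emitted.
    """
    if hop_samples < 1:
        raise ValueError("hop_samples must be >= 1")
    features = trial.as_array()
    T = features.shape[0]
    n_steps = window_count(T, hop_samples)
    if n_steps < 1:
        raise ValueError(
            f"trial too short to segment: {T} samples < {WINDOW_SAMPLES}"
        )
    return WindowedTrial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        group=trial.group,
        label=trial.label,
        features=features,
        hop_samples=hop_samples,
        n_steps=n_steps,
    )


@dataclass
class WindowedDataset:
    """Windowed trials of a cohort with a common step coverage."""

    trials: list[WindowedTrial]
    hop_samples: int
    n_steps: int  # maximum step index common to all trials

    @classmethod
    def from_trials(cls, trials: list[WindowedTrial]) -> "WindowedDataset":
        if not trials:
            raise ValueError("no trials to build a WindowedDataset from")
        hops = {t.hop_samples for t in trials}
        if len(hops) != 1:
            raise ValueError("trials were segmented with different hops")
        return cls(
            trials=trials,
            hop_samples=hops.pop(),
            n_steps=min(t.n_steps for t in trials),
        )

    @property
    def subject_ids(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def for_subjects(self, subject_ids) -> list[WindowedTrial]:
        wanted = set(subject_ids)
        return [t for t in self.trials if t.subject_id in wanted]


def segment_cohort(
    trials: list[TrialFeatures], hop_samples: int = 12
) -> WindowedDataset:
    return WindowedDataset.from_trials(
        [segment_trial(t, hop_samples) for t in trials]
    )


def evaluation_steps(dataset: WindowedDataset, horizon_s: float) -> list[int]:
    """Step indices whose window end time is within the horizon.

    A horizon beyond the shortest trial is truncated (the common step
    coverage bounds the report).
    """
    import warnings

    ends = window_end_times(dataset.n_steps, dataset.hop_samples)
    steps = [int(k) for k in np.arange(1, dataset.n_steps + 1)[ends <= horizon_s]]
    if horizon_s > ends[-1] + 1e-9:
        warnings.warn(
            f"horizon {horizon_s} s exceeds common trial coverage "
            f"({ends[-1]:.2f} s); truncated",
            stacklevel=2,
        )
    return steps
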