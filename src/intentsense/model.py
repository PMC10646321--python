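"""Model/Results interface over the full intent-sensing pipeline.

:class:`IntentSensingModel` is built from cohort data (a synthetic
:class:`~intentsense.synthetic.CohortData`, an on-disk
:class:`~intentsense.io.DiskCohort`, or preprocessed trial features);
``fit()`` runs preprocessing, segmentation and the leave-one-subject-out
evaluation of every requested fusion method and returns an
:class:`IntentSensingResults` carrying the accuracy-vs-time curves,
their bootstrap confidence intervals, Spearman monotonicity statistics,
the naive upper bound, and group comparisons, with ``summary()`` and
tidy-CSV export.

Example
-------
>>> from intentsense import GeneratorConfig, PipelineConfig
>>> from intentsense.model import IntentSensingModel
>>> cfg = GeneratorConfig(n_patients=3, n_controls=3)
>>> model = IntentSensingModel.from_synthetic(cfg, seed=11)
>>> res = model.fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ALL_SENSORS, GeneratorConfig, PipelineConfig
from .evaluation import (
    AccuracyCurve,
    LosoOutcome,
    MonotonicityResult,
    compare_groups,
    naive_gap,
    run_loso,
    spearman_monotonicity,
)
from .preprocessing import TrialFeatures, preprocess_trial
from .segmentation import WindowedDataset, segment_cohort
from .synthetic import CohortData, generate_cohort_dataset

__all__ = ["IntentSensingModel", "IntentSensingResults"]


class IntentSensingModel:
    """Multi-modal, time-segmented intent-sensing pipeline as a model object.

    Parameters
    ----------
    data :
        Cohort source with ``iter_trials()`` and per-subject
        ``calibration()`` (synthetic or disk-backed), or a pre-built list
        of :class:`TrialFeatures`.
    pipeline :
        Windowing, backend, fusion-method and seed settings.
    """

    def __init__(self, data, pipeline: PipelineConfig | None = None):
        self.pipeline = pipeline or PipelineConfig()
        self.data = data
        self._features: list[TrialFeatures] | None = (
            list(data) if isinstance(data, list) else None
        )
        self._dataset: WindowedDataset | None = None

    @classmethod
    def from_synthetic(
        cls,
        generator: GeneratorConfig | None = None,
        seed: int = 0,
        pipeline: PipelineConfig | None = None,
    ) -> "IntentSensingModel":
        """Generate a seeded synthetic cohort and wrap it in a model."""
        pipeline = pipeline or PipelineConfig(cohort_seed=seed)
        data = generate_cohort_dataset(generator, seed=seed)
        return cls(data, pipeline)

    @classmethod
    def from_directory(
        cls, path, pipeline: PipelineConfig | None = None
    ) -> "IntentSensingModel":
        """Read a cohort from the on-disk CSV/WAV/manifest layout."""
        from .io import read_cohort

        return cls(read_cohort(path), pipeline)

    # ------------------------------------------------------------------

    def preprocess(self, progress: bool = False) -> list[TrialFeatures]:
        """Calibration-correct, heading-randomise and featurise every trial.

        Heading seeds derive deterministically from the pipeline's cohort
        seed and the trial index. Raw waveforms are released after
        featurisation.
        """
        if self._features is not None:
            return self._features
        rng = np.random.default_rng([self.pipeline.cohort_seed, 7])
        features = []
        for idx, trial in enumerate(self.data.iter_trials()):
            calibration = self.data.calibration(trial.subject_id)
            features.append(
                preprocess_trial(
                    trial,
                    calibration,
                    heading_seed=int(rng.integers(0, 2**31 - 1)),
                    full_3d_heading=self.pipeline.full_3d_heading,
                )
            )
            if progress and (idx + 1) % 10 == 0:
                print(f"preprocessed {idx + 1} trials")
        self._features = features
        return features

    def segment(self) -> WindowedDataset:
        if self._dataset is None:
            self._dataset = segment_cohort(
                self.preprocess(), self.pipeline.hop_samples
            )
        return self._dataset

    def fit(self, progress: bool = False) -> "IntentSensingResults":
        """Run the LOSO evaluation and package the results."""
        dataset = self.segment()
        outcome = run_loso(dataset, self.pipeline, progress=progress)
        monotonicity = {
            key: spearman_monotonicity(curve)
            for key, curve in outcome.curves.items()
        }
        groups = {}
        if len(set(outcome.trial_groups)) > 1:
            groups = {
                key: compare_groups(outcome, key, self.pipeline)
                for key in outcome.curves
            }
        return IntentSensingResults(
            model=self,
            outcome=outcome,
            monotonicity=monotonicity,
            group_reports=groups,
        )


@dataclass
class IntentSensingResults:
    """Fitted accuracy curves, monotonicity statistics and diagnostics."""

    model: IntentSensingModel
    outcome: LosoOutcome
    monotonicity: dict[tuple[str, str], MonotonicityResult]
    group_reports: dict = field(default_factory=dict)

    # -- accessors ------------------------------------------------------

    @property
    def curves(self) -> dict[tuple[str, str], AccuracyCurve]:
        return self.outcome.curves

    @property
    def sensor_curves(self) -> dict[str, AccuracyCurve]:
        return self.outcome.sensor_curves

    @property
    def naive_bound(self):
        return self.outcome.naive_bound

    def curve(self, method: str, scope: str = "network") -> AccuracyCurve:
        return self.outcome.curves[(method, scope)]

    def accuracy_gap_to_bound(self, method: str, scope: str = "network") -> dict:
        return naive_gap(self.curve(method, scope), self.outcome.naive_bound)

    # -- presentation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(method, scope, step) accuracy table."""
        rows = []
        for (method, scope), curve in self.outcome.curves.items():
            mono = self.monotonicity[(method, scope)]
            for i, step in enumerate(curve.steps):
                rows.append(
                    {
                        "method": method,
                        "scope": scope,
                        "step": int(step),
                        "end_time_s": float(curve.end_times_s[i]),
                        "accuracy": float(curve.accuracy[i]),
                        "ci_low": float(curve.ci95[0, i]),
                        "ci_high": float(curve.ci95[1, i]),
                        "spearman_rs": mono.rs,
                        "n_trials": curve.n_trials,
                    }
                )
        for sensor, curve in self.outcome.sensor_curves.items():
            for i, step in enumerate(curve.steps):
                rows.append(
                    {
                        "method": "majority_full",
                        "scope": sensor,
                        "step": int(step),
                        "end_time_s": float(curve.end_times_s[i]),
                        "accuracy": float(curve.accuracy[i]),
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "spearman_rs": np.nan,
                        "n_trials": curve.n_trials,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted evaluation."""
        lines = []
        out = self.outcome
        n_subj = len(set(out.trial_subjects))
        lines.append("Intent-sensing LOSO evaluation")
        lines.append("=" * 64)
        lines.append(
            f"subjects: {n_subj}   trials: {len(out.trial_subjects)}   "
            f"steps: {len(out.steps)} (0.5-{out.end_times_s[-1]:.2f} s)"
        )
        lines.append(
            f"backend: {self.model.pipeline.backend}   "
            f"hop: {self.model.pipeline.hop_samples} samples"
        )
        lines.append("")
        lines.append(
            f"{'method':<18}{'scope':<10}{'acc@0.5s':>10}{'max acc':>10}"
            f"{'terminal':>10}{'Spearman':>10}"
        )
        lines.append("-" * 68)
        for (method, scope), curve in sorted(out.curves.items()):
            rs = self.monotonicity[(method, scope)].rs
            lines.append(
                f"{method:<18}{scope:<10}{curve.accuracy[0]:>10.4f}"
                f"{curve.accuracy.max():>10.4f}{curve.accuracy[-1]:>10.4f}{rs:>10.3f}"
            )
        lines.append("")
        lines.append("individual sensors (majority voting over time):")
        for sensor in ALL_SENSORS:
            c = out.sensor_curves[sensor]
            lines.append(
                f"  {sensor:<10} acc@0.5s {c.accuracy[0]:.4f}   "
                f"terminal {c.accuracy[-1]:.4f}"
            )
        nb = out.naive_bound.terminal
        lines.append("")
        lines.append(
            f"naive upper bound (terminal): {nb.p_bound:.6f} from per-sensor "
            "accuracies "
            + ", ".join(f"{s}={a:.3f}" for s, a in nb.sensor_accuracies.items())
        )
        if self.group_reports:
            lines.append("")
            lines.append("patient vs control (threshold-crossing step):")
            for (method, scope), rep in sorted(self.group_reports.items()):
                parts = []
                for g, r in rep.items():
                    step = r["threshold_step"]
                    parts.append(f"{g}: {step if step is not None else '-'}")
                lines.append(f"  {method}/{scope}: " + "   ".join(parts))
        return "\n".join(lines)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_accuracy(self, scope: str = "network", ax=None):
        """Accuracy vs time for every method at one scope (minimal styling)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for (method, sc), curve in sorted(self.outcome.curves.items()):
            if sc != scope:
                continue
            ax.plot(curve.end_times_s, curve.accuracy, label=method)
            if curve.ci95 is not None:
                ax.fill_between(
                    curve.end_times_s, curve.ci95[0], curve.ci95[1], alpha=0.15
                )
        ax.set_xlabel("time after activity inception (s)")
        ax.set_ylabel("accuracy")
        ax.set_title(f"accuracy vs. time ({scope})")
        ax.legend()
        return ax
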