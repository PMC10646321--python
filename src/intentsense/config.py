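"""Configuration dataclasses and YAML (de)serialisation.

Two groups of settings exist: :class:`GeneratorConfig` fixes the synthetic
cohort (sizes, durations, signature contrast, noise, tremor range) and
:class:`PipelineConfig` fixes the analysis chain (windowing, horizon,
confusion-matrix smoothing, classifier backend, fusion methods, seeds).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Five body-worn IMU streams (upper/lower x left/right arm, head) plus audio.
IMU_STREAMS = ("imu_ul", "imu_ur", "imu_ll", "imu_lr", "imu_head")
AUDIO_STREAM = "audio"
ALL_SENSORS = IMU_STREAMS + (AUDIO_STREAM,)

#: The three activity-of-daily-living intent classes.
ACTIVITIES = ("door", "cardigan", "toast")

FS_IMU = 50  # Hz
FS_AUDIO = 44_100  # Hz
AUDIO_SAMPLES_PER_IMU_SAMPLE = 882  # 44_100 / 50

#: Fusion methods: Bayes weighted per (sensor, step); Bayes weighted per
#: sensor with step-pooled matrices; majority voting trained on the full
#: training set; majority voting trained on half the training set.
FUSION_METHODS = (
    "bayes_sensor_time",
    "bayes_sensor_only",
    "majority_full",
    "majority_half",
)


@dataclass
class GeneratorConfig:
    """Settings for the synthetic multi-sensor cohort generator.

    ``contrast`` scales every class-dependent term in the signal model;
    at 0 the three activity classes are identically distributed (a null
    cohort), at the default 1.0 single-sensor accuracy of the lightweight
    backend sits in the 0.7-0.9 band with audio the weakest sensor.
    ``noise`` scales every trial-level stochastic term (channel noise,
    audio babble, timing/phase jitter), so 0 makes repeats of an activity
    bit-identical.
    """

    n_patients: int = 15
    n_controls: int = 19
    trial_duration_s: float = 21.0
    calibration_duration_s: float = 2.0
    n_repeats: int = 3
    contrast: float = 1.0
    noise: float = 1.0
    tremor_amplitude_range: tuple[float, float] = (0.5, 1.5)  # m/s^2, patients
    patient_variability_range: tuple[float, float] = (1.15, 1.6)
    control_variability_range: tuple[float, float] = (0.8, 1.2)
    motion_scale_range: tuple[float, float] = (0.8, 1.2)
    misalignment_max_rad: float = 0.35
    babble_level: float = 0.10
    audio_tone_level: float = 0.002
    audio_event_level: float = 0.04
    accel_noise_sd: float = 2.0  # m/s^2
    gyro_noise_sd: float = 0.6  # rad/s
    mag_noise_sd: float = 0.1  # unitless (normalised field)

    def __post_init__(self) -> None:
        if self.trial_duration_s < 21.0:
            raise ValueError(
                "trial_duration_s must be >= 21 s to cover the 0.5-20.5 s "
                "evaluation horizon"
            )
        if self.contrast < 0 or self.noise < 0:
            raise ValueError("contrast and noise must be non-negative")


@dataclass
class PipelineConfig:
    """Settings for preprocessing, segmentation, training and fusion."""

    window_ms: float = 500.0
    overlap_ms: float = 250.0
    horizon_s: float = 20.5
    smoothing_alpha: float = 1.0
    backend: str = "lightweight"  # or "lstm"
    methods: Sequence[str] = FUSION_METHODS
    full_3d_heading: bool = False  # yaw-only heading randomisation by default
    soft_votes: bool = False  # Bayes fusion of hard argmax votes (default path)
    log_domain: bool = True
    n_bootstrap: int = 1000
    threshold_accuracy: float = 0.99995  # "100.00% to two decimal places"
    # LSTM backend hyperparameters
    epochs: int = 50
    hidden_units: int = 15  # per direction of the bidirectional layer
    learning_rate: float = 1e-3
    batch_size: int = 512
    # independent seed streams
    cohort_seed: int = 0
    split_seed: int = 1
    training_seed: int = 2
    bootstrap_seed: int = 3

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * FS_IMU / 1000.0))  # 25 at defaults

    @property
    def hop_samples(self) -> int:
        """Window advance in samples.

        250 ms at 50 Hz is 12.5 samples; the hop is floored to 12 samples
        (240 ms advance, 260 ms overlap), a documented deviation from the
        nominal 250 ms.
        """
        hop = int((self.window_ms - self.overlap_ms) * FS_IMU / 1000.0)
        if hop < 1:
            raise ValueError("window/overlap combination yields hop < 1 sample")
        return hop

    def __post_init__(self) -> None:
        if self.backend not in ("lightweight", "lstm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        unknown = set(self.methods) - set(FUSION_METHODS)
        if unknown:
            raise ValueError(
                f"unknown fusion methods {sorted(unknown)}; "
                f"valid: {list(FUSION_METHODS)}"
            )


def _from_mapping(cls, mapping: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise KeyError(
            f"unknown {cls.__name__} config key(s): {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}"
        )
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            target = f.type or ""
            if "tuple" in str(target):
                kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[GeneratorConfig, PipelineConfig]:
    """Read a YAML file with optional ``generator:`` and ``pipeline:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise KeyError("config file must contain a mapping")
    unknown = set(raw) - {"generator", "pipeline"}
    if unknown:
        raise KeyError(f"unknown top-level config key(s): {sorted(unknown)}")
    gen = _from_mapping(GeneratorConfig, raw.get("generator", {}) or {})
    pipe = _from_mapping(PipelineConfig, raw.get("pipeline", {}) or {})
    return gen, pipe


def dump_config(gen: GeneratorConfig, pipe: PipelineConfig, path: str | Path) -> None:
    payload = {
        "generator": dataclasses.asdict(gen),
        "pipeline": {**dataclasses.asdict(pipe), "methods": list(pipe.methods)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
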