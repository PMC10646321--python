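"""On-disk cohort layout: CSV per trial, 16-bit PCM WAV audio, JSON manifest.

Layout (one directory per subject)::

    <root>/manifest.json
    <root>/<subject_id>/<trial_id>_imu.csv     # t_index, stream_id, 9 channels,
                                               # 9 rotation entries (row-major)
    <root>/<subject_id>/<trial_id>_audio.wav   # mono, 16-bit PCM, 44 100 Hz
    <root>/<subject_id>/<subject_id>_calibration_{imu.csv,audio.wav}

This writer's layout is also the reader contract for real recordings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import FS_AUDIO, GeneratorConfig, IMU_STREAMS
from .synthetic import CohortData, RawTrial, SubjectProfile, TrialSpec, generate_trial

__all__ = ["write_cohort", "read_cohort", "DiskCohort"]

_CHANNEL_COLS = [
    "mag_x", "mag_y", "mag_z",
    "gyro_x", "gyro_y", "gyro_z",
    "accel_x", "accel_y", "accel_z",
]
_ROT_COLS = [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]


def _write_trial(trial: RawTrial, subject_dir: Path) -> dict:
    T = trial.n_samples
    frames = []
    for i, stream in enumerate(IMU_STREAMS):
        df = pd.DataFrame(trial.imu[i], columns=_CHANNEL_COLS)
        df.insert(0, "stream_id", stream)
        df.insert(0, "t_index", np.arange(T))
        df[_ROT_COLS] = trial.imu_rotation[i].reshape(T, 9)
        frames.append(df)
    imu_path = subject_dir / f"{trial.trial_id}_imu.csv"
    pd.concat(frames, ignore_index=True).to_csv(imu_path, index=False, float_format="%.9g")
    wav_path = subject_dir / f"{trial.trial_id}_audio.wav"
    pcm = np.clip(trial.audio, -1.0, 1.0)
    wavfile.write(wav_path, FS_AUDIO, (pcm * 32767).astype(np.int16))
    return {
        "trial_id": trial.trial_id,
        "subject_id": trial.subject_id,
        "label": trial.label,
        "imu_csv": str(imu_path.relative_to(subject_dir.parent)),
        "audio_wav": str(wav_path.relative_to(subject_dir.parent)),
    }


def write_cohort(data: CohortData, out_dir: str | Path) -> Path:
    """Materialise a synthetic cohort on disk; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_entries = []
    for spec in data.trial_specs:
        subject_dir = out_dir / spec.subject.subject_id
        subject_dir.mkdir(exist_ok=True)
        trial = generate_trial(spec, data.config)
        trial_entries.append(_write_trial(trial, subject_dir))
    cal_entries = {}
    for profile in data.profiles:
        subject_dir = out_dir / profile.subject_id
        subject_dir.mkdir(exist_ok=True)
        cal = data.calibration(profile.subject_id)
        cal_entries[profile.subject_id] = _write_trial(cal, subject_dir)
    manifest = {
        "profiles": [dataclasses.asdict(p) for p in data.profiles],
        "trials": trial_entries,
        "calibrations": cal_entries,
        "generator_config": dataclasses.asdict(data.config),
        "seed": data.seed,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def _read_trial(root: Path, entry: dict, group: str) -> RawTrial:
    df = pd.read_csv(root / entry["imu_csv"])
    T = int(df["t_index"].max()) + 1
    imu = np.empty((len(IMU_STREAMS), T, 9))
    rot = np.empty((len(IMU_STREAMS), T, 3, 3))
    for i, stream in enumerate(IMU_STREAMS):
        block = df[df["stream_id"] == stream].sort_values("t_index")
        if len(block) != T:
            raise ValueError(
                f"malformed trial file {entry['imu_csv']}: stream {stream!r} "
                f"has {len(block)} samples, expected {T}"
            )
        imu[i] = block[_CHANNEL_COLS].to_numpy()
        rot[i] = block[_ROT_COLS].to_numpy().reshape(T, 3, 3)
    fs, pcm = wavfile.read(root / entry["audio_wav"])
    if fs != FS_AUDIO:
        raise ValueError(f"expected {FS_AUDIO} Hz audio, got {fs}")
    audio = pcm.astype(float) / 32767.0
    return RawTrial(
        trial_id=entry["trial_id"],
        subject_id=entry["subject_id"],
        group=group,
        label=entry["label"],
        imu=imu,
        imu_rotation=rot,
        audio=audio,
    )


class DiskCohort:
    """Lazy reader over the on-disk cohort layout.

    Mirrors the :class:`~intentsense.synthetic.CohortData` access surface
    (profiles, ``iter_trials``, per-subject ``calibration``) so the
    evaluation pipeline is agnostic to where trials come from.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        manifest_path = self.root / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.json under {self.root}")
        manifest = json.loads(manifest_path.read_text())
        self.profiles = [SubjectProfile(**p) for p in manifest["profiles"]]
        self._trial_entries = manifest["trials"]
        self._cal_entries = manifest["calibrations"]
        self.config = GeneratorConfig(**manifest.get("generator_config", {}))
        self.seed = manifest.get("seed", 0)
        self._groups = {p.subject_id: p.group for p in self.profiles}

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]

    @property
    def groups(self) -> dict[str, str]:
        return dict(self._groups)

    def calibration(self, subject_id: str) -> RawTrial:
        return _read_trial(self.root, self._cal_entries[subject_id], self._groups[subject_id])

    def iter_trials(self):
        for entry in self._trial_entries:
            yield _read_trial(self.root, entry, self._groups[entry["subject_id"]])


def read_cohort(root: str | Path) -> DiskCohort:
    return DiskCohort(root)
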