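"""Preprocessing: calibration correction, heading randomisation, MFCCs.

Turns a raw trial (five 9-channel IMU streams with orientation matrices,
one 44.1 kHz audio waveform) into six aligned 50 Hz, 18-feature streams:

* each IMU stream contributes its 9 sensor channels plus the 9 entries of
  its per-sample rotation matrix (row-major);
* the audio contributes the first 18 mel-frequency cepstral coefficients
  of each 882-sample frame (one frame per IMU sample), computed with an
  882-point Hamming window.

MFCC dialect (fixed and documented; no bit-compatibility with any
particular toolbox is claimed): 26 triangular mel filters spanning
0-22 050 Hz on the HTK mel scale, natural log with a 1e-10 floor, and an
orthonormal DCT-II; coefficient 1 is the energy (0th DCT) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .config import (
    ALL_SENSORS,
    AUDIO_SAMPLES_PER_IMU_SAMPLE,
    AUDIO_STREAM,
    FS_AUDIO,
    FS_IMU,
    IMU_STREAMS,
)
from .rotations import is_rotation, project_to_rotation, random_rotation, rotation_about_z
from .synthetic import RawTrial

__all__ = [
    "FeatureStream",
    "TrialFeatures",
    "mean_calibration_rotation",
    "apply_calibration",
    "random_heading_rotation",
    "frame_audio",
    "mfcc_features",
    "assemble_streams",
    "preprocess_trial",
    "Standardizer",
    "N_MFCC",
    "N_MEL_FILTERS",
]

N_FEATURES = 18
N_MFCC = 18
N_MEL_FILTERS = 26
LOG_FLOOR = 1e-10

_IMU_FEATURE_NAMES = (
    ["mag_x", "mag_y", "mag_z", "gyro_x", "gyro_y", "gyro_z", "accel_x", "accel_y", "accel_z"]
    + [f"rot_{i}{j}" for i in range(1, 4) for j in range(1, 4)]
)
_AUDIO_FEATURE_NAMES = [f"mfcc_{k}" for k in range(1, N_MFCC + 1)]


@dataclass
class FeatureStream:
    """One sensor's 50 Hz, 18-feature time series."""

    sensor_id: str
    features: np.ndarray  # (T, 18)
    feature_names: list[str]
    rate_hz: int = FS_IMU

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(
                f"FeatureStream must be (T, {N_FEATURES}), got {self.features.shape}"
            )


@dataclass
class TrialFeatures:
    """All six feature streams of one trial, plus its provenance."""

    trial_id: str
    subject_id: str
    group: str
    label: str
    streams: dict[str, FeatureStream]

    @property
    def n_samples(self) -> int:
        return next(iter(self.streams.values())).features.shape[0]

    def as_array(self, sensors: tuple[str, ...] = ALL_SENSORS) -> np.ndarray:
        """Stack streams into a (T, n_sensors, 18) array in ``sensors`` order."""
        return np.stack([self.streams[s].features for s in sensors], axis=1)


# --------------------------------------------------------------------------
# rotation correction


def mean_calibration_rotation(calibration: RawTrial, stream_id: str) -> np.ndarray:
    """Mean orientation during the calibration pose, projected onto SO(3).

    The element-wise mean of the per-sample rotation matrices is not
    itself a rotation; it is projected onto the nearest rotation matrix
    (Frobenius norm) by SVD with the determinant forced to +1.
    """
    idx = IMU_STREAMS.index(stream_id)
    mats = calibration.imu_rotation[idx]
    if mats.shape[0] == 0:
        raise ValueError(f"empty calibration segment for stream {stream_id!r}")
    return project_to_rotation(mats.mean(axis=0))


def _rotate_trial(trial: RawTrial, per_stream_rot: dict[str, np.ndarray]) -> RawTrial:
    """Premultiply each IMU stream's vector modalities and orientation by a rotation."""
    imu = trial.imu.copy()
    imu_rot = trial.imu_rotation.copy()
    for i, stream in enumerate(IMU_STREAMS):
        R = per_stream_rot[stream]
        for c0 in (0, 3, 6):  # mag, gyro, accel blocks
            imu[i, :, c0 : c0 + 3] = imu[i, :, c0 : c0 + 3] @ R.T
        imu_rot[i] = np.einsum("ij,tjk->tik", R, imu_rot[i])
    return RawTrial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        group=trial.group,
        label=trial.label,
        imu=imu,
        imu_rotation=imu_rot,
        audio=trial.audio,
        calibration=trial.calibration,
        fs_imu=trial.fs_imu,
        fs_audio=trial.fs_audio,
    )


def apply_calibration(trial: RawTrial, rotations: dict[str, np.ndarray]) -> RawTrial:
    """Rotate every 3-axis modality by the inverse of its calibration rotation.

    ``rotations`` maps each IMU stream to its mean calibration rotation;
    the per-sample rotation-matrix channel is composed with the same
    inverse.  The audio channel is untouched.
    """
    inv = {}
    for stream in IMU_STREAMS:
        if stream not in rotations:
            raise ValueError(f"missing calibration rotation for stream {stream!r}")
        R = np.asarray(rotations[stream], dtype=float)
        if not is_rotation(R):
            raise ValueError(f"calibration matrix for {stream!r} is not a rotation")
        inv[stream] = R.T
    return _rotate_trial(trial, inv)


def random_heading_rotation(
    trial: RawTrial, seed: int, full_3d: bool = False
) -> RawTrial:
    """Apply one random per-trial heading rotation to all five IMU streams.

    By default the rotation is yaw-only (about the global vertical),
    with angle uniform on [0, 2*pi) drawn deterministically from ``seed``
    — it removes the starting direction without corrupting the gravity
    reference.  ``full_3d`` applies a uniform random 3D rotation instead.
    """
    rng = np.random.default_rng(seed)
    if full_3d:
        R = random_rotation(rng, np.pi)
    else:
        R = rotation_about_z(rng.uniform(0.0, 2 * np.pi))
    return _rotate_trial(trial, {s: R for s in IMU_STREAMS})


# --------------------------------------------------------------------------
# audio


def frame_audio(audio: np.ndarray, imu_length: int | None = None) -> np.ndarray:
    """Cut a waveform into contiguous non-overlapping 882-sample frames.

    One frame per IMU sample; surplus trailing samples are discarded.
    Returns an (imu_length, 882) array.
    """
    audio = np.asarray(audio)
    if imu_length is None:
        imu_length = len(audio) // AUDIO_SAMPLES_PER_IMU_SAMPLE
    needed = AUDIO_SAMPLES_PER_IMU_SAMPLE * imu_length
    if len(audio) < needed:
        raise ValueError(
            f"audio too short: {len(audio)} samples < "
            f"{AUDIO_SAMPLES_PER_IMU_SAMPLE} x {imu_length}"
        )
    return audio[:needed].reshape(imu_length, AUDIO_SAMPLES_PER_IMU_SAMPLE)


def mel_filterbank(
    n_filters: int = N_MEL_FILTERS,
    n_fft: int = AUDIO_SAMPLES_PER_IMU_SAMPLE,
    fs: int = FS_AUDIO,
) -> np.ndarray:
    """Triangular mel filterbank matrix, (n_filters, n_fft//2 + 1)."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    n_bins = n_fft // 2 + 1
    mel_points = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_filters + 2)
    hz_points = mel_to_hz(mel_points)
    bin_freqs = np.arange(n_bins) * fs / n_fft
    bank = np.zeros((n_filters, n_bins))
    for m in range(n_filters):
        lo, mid, hi = hz_points[m], hz_points[m + 1], hz_points[m + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


_MEL_BANK: np.ndarray | None = None
_HAMMING = np.hamming(AUDIO_SAMPLES_PER_IMU_SAMPLE)  # symmetric Hamming window


def mfcc_features(frames: np.ndarray) -> FeatureStream:
    """First 18 MFCCs of each 882-sample frame, as a 50 Hz feature stream.

    Per frame: Hamming window, power spectrum, 26-filter mel filterbank,
    natural log (floored at 1e-10, so silence maps to a finite constant
    pattern), orthonormal DCT-II, coefficients 1-18 (coefficient 1 being
    the 0th, energy, coefficient).
    """
    global _MEL_BANK
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] == 0:
        raise ValueError("no audio frames")
    if frames.shape[1] != AUDIO_SAMPLES_PER_IMU_SAMPLE:
        raise ValueError(
            f"frames must have {AUDIO_SAMPLES_PER_IMU_SAMPLE} samples, "
            f"got {frames.shape[1]}"
        )
    if _MEL_BANK is None:
        _MEL_BANK = mel_filterbank()
    windowed = frames * _HAMMING[None, :]
    power = np.abs(rfft(windowed, axis=1)) ** 2 / AUDIO_SAMPLES_PER_IMU_SAMPLE
    energies = power @ _MEL_BANK.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :N_MFCC]
    return FeatureStream(
        sensor_id=AUDIO_STREAM, features=coeffs, feature_names=list(_AUDIO_FEATURE_NAMES)
    )


# --------------------------------------------------------------------------
# assembly


def assemble_streams(trial: RawTrial) -> dict[str, FeatureStream]:
    """Six aligned 18-feature streams (5 IMU + audio MFCC), all length T."""
    T = trial.n_samples
    streams: dict[str, FeatureStream] = {}
    for i, stream in enumerate(IMU_STREAMS):
        feats = np.concatenate(
            [trial.imu[i], trial.imu_rotation[i].reshape(T, 9)], axis=1
        )
        streams[stream] = FeatureStream(
            sensor_id=stream, features=feats, feature_names=list(_IMU_FEATURE_NAMES)
        )
    audio_stream = mfcc_features(frame_audio(trial.audio, T))
    if audio_stream.features.shape[0] != T:
        raise ValueError("audio/IMU stream length mismatch")
    streams[AUDIO_STREAM] = audio_stream
    return streams


def preprocess_trial(
    trial: RawTrial,
    calibration: RawTrial,
    heading_seed: int,
    full_3d_heading: bool = False,
) -> TrialFeatures:
    """Full preprocessing chain for one trial.

    Calibration rotation correction (inverse mean calibration rotation,
    per stream), random per-trial heading rotation, then feature-stream
    assembly.  Standardisation is *not* applied here; it is fitted on the
    training split only (see :class:`Standardizer`).
    """
    rotations = {
        s: mean_calibration_rotation(calibration, s) for s in IMU_STREAMS
    }
    corrected = apply_calibration(trial, rotations)
    randomized = random_heading_rotation(corrected, heading_seed, full_3d=full_3d_heading)
    return TrialFeatures(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        group=trial.group,
        label=trial.label,
        streams=assemble_streams(randomized),
    )


class Standardizer:
    """Per-sensor, per-feature z-scoring with training-split statistics.

    Constant features get unit fallback scale (no division by zero).
    Fitting on training subjects only and transforming test subjects with
    those statistics is the caller's leakage contract.
    """

    def __init__(self) -> None:
        self.mean_: dict[str, np.ndarray] | None = None
        self.scale_: dict[str, np.ndarray] | None = None

    def fit(self, trials: list[TrialFeatures]) -> "Standardizer":
        if not trials:
            raise ValueError("cannot fit Standardizer on an empty training split")
        self.mean_, self.scale_ = {}, {}
        for sensor in ALL_SENSORS:
            stacked = np.concatenate([t.streams[sensor].features for t in trials])
            mu = stacked.mean(axis=0)
            sd = stacked.std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            self.mean_[sensor] = mu
            self.scale_[sensor] = sd
        return self

    def transform(self, trial: TrialFeatures) -> TrialFeatures:
        if self.mean_ is None:
            raise RuntimeError("Standardizer is not fitted")
        streams = {}
        for sensor, fs in trial.streams.items():
            z = (fs.features - self.mean_[sensor]) / self.scale_[sensor]
            streams[sensor] = FeatureStream(
                sensor_id=sensor, features=z, feature_names=list(fs.feature_names)
            )
        return TrialFeatures(
            trial_id=trial.trial_id,
            subject_id=trial.subject_id,
            group=trial.group,
            label=trial.label,
            streams=streams,
        )
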