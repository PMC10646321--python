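"""Seeded synthetic multi-sensor cohort generator.

Emulates the statistical structure of a wearable-sensor intent-sensing
study: a cohort of patients (with Parkinsonian tremor and higher motor
variability) and controls, each performing three activities of daily
living (opening a door, buttoning a cardigan, making toast) three times,
recorded by five body-worn 9-channel IMUs at 50 Hz (plus a per-sample
orientation rotation matrix) and one 44.1 kHz room microphone.

Signal model
------------
Each IMU stream carries a per-subject mounting misalignment rotation
``R0`` composed with a slow, class-specific *posture* rotation ``P_c(t)``
that ramps in over the first ~2 s of the activity.  The accelerometer
reads gravity through that orientation, the magnetometer reads a fixed
global field through it, the gyroscope reads its angular velocity, and
the rotation-matrix channel reports the orientation itself.  Class
identity therefore lives in slowly varying feature *means* whose
separation grows over the trial, which is what gives downstream
accuracy-vs-time curves their rising shape.  Patients additionally carry
an amplitude-modulated 4-6 Hz tremor (orientation jitter plus a direct
accelerometer component) and larger subject-level variability.

The microphone picks up band-limited babble (conversation emulated as
noise, never speech), a faint sustained class-specific tone and a train
of class-specific sound events (key-turn-like tone bursts, button
clicks, a toaster-like buzz).

Every class-dependent term scales with ``GeneratorConfig.contrast``
(contrast 0 is an exact null: the three classes are identically
distributed) and every trial-level stochastic term scales with
``GeneratorConfig.noise`` (noise 0 with zero tremor makes repeats of an
activity bit-identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy import signal as sp_signal

from .config import (
    ACTIVITIES,
    AUDIO_SAMPLES_PER_IMU_SAMPLE,
    FS_AUDIO,
    FS_IMU,
    IMU_STREAMS,
    GeneratorConfig,
)
from .rotations import GRAVITY, random_rotation, rotation_about_z, rotvec_to_matrix

__all__ = [
    "SubjectProfile",
    "TrialSpec",
    "RawTrial",
    "generate_cohort",
    "plan_trials",
    "generate_trial",
    "generate_calibration",
    "CohortData",
    "generate_cohort_dataset",
]

MIN_TRIAL_DURATION_S = 21.0  # must cover the 0.5-20.5 s evaluation horizon

_MAG_FIELD = np.array([0.6, 0.0, 0.8])  # unit-norm global magnetic field

# Per-stream base oscillation frequency (Hz) and informativeness gain.
_BASE_FREQ = {"imu_ul": 1.1, "imu_ur": 1.3, "imu_ll": 0.9, "imu_lr": 1.5, "imu_head": 0.7}
_STREAM_GAIN = {"imu_ul": 1.0, "imu_ur": 1.1, "imu_ll": 0.95, "imu_lr": 1.15, "imu_head": 0.75}

_SQ2 = 1.0 / np.sqrt(2.0)
# Class-specific posture rotation: (axis, peak angle rad) per stream.
# Because every trial receives a random yaw, the classes must separate in
# yaw-invariant structure: the *magnitude* of each stream's tilt away from
# vertical (and its z-axis content), not the horizontal direction of tilt.
_POSTURE: dict[str, dict[str, tuple[tuple[float, float, float], float]]] = {
    "door": {
        "imu_ul": ((1, 0, 0), 0.30),
        "imu_ur": ((0, 1, 0), 0.75),
        "imu_ll": ((1, 0, 0), 0.25),
        "imu_lr": ((0, 1, 0), 0.80),
        "imu_head": ((1, 0, 0), 0.10),
    },
    "cardigan": {
        "imu_ul": ((0, 1, 0), 0.65),
        "imu_ur": ((1, 0, 0), 0.40),
        "imu_ll": ((0, 1, 0), 0.70),
        "imu_lr": ((1, 0, 0), 0.40),
        "imu_head": ((0, 1, 0), 0.25),
    },
    "toast": {
        "imu_ul": ((_SQ2, _SQ2, 0), 0.45),
        "imu_ur": ((_SQ2, -_SQ2, 0), 0.55),
        "imu_ll": ((0, _SQ2, _SQ2), 0.45),
        "imu_lr": ((_SQ2, 0, _SQ2), 0.60),
        "imu_head": ((_SQ2, _SQ2, 0), 0.17),
    },
}

# Class-specific limb oscillation frequency (Hz).
_CLASS_FREQ = {"door": 2.1, "cardigan": 2.7, "toast": 1.6}
# Audio: sustained tone frequency and event pattern per class.
_AUDIO_TONE_HZ = {"door": 820.0, "cardigan": 1560.0, "toast": 340.0}
_EVENT_INTERVAL_S = {"door": 2.2, "cardigan": 1.4, "toast": 2.8}


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject parameters of the generator."""

    subject_id: str
    group: Literal["patient", "control"]
    motion_scale: float
    tremor_amplitude: float  # m/s^2; 0 for controls
    variability: float  # per-subject noise multiplier, > 0
    rng_seed: int

    def __post_init__(self) -> None:
        if self.tremor_amplitude < 0:
            raise ValueError("tremor_amplitude must be >= 0")
        if self.variability <= 0:
            raise ValueError("variability must be > 0")


@dataclass(frozen=True)
class TrialSpec:
    subject: SubjectProfile
    activity: str
    repeat_index: int  # 1..n_repeats
    duration_s: float
    trial_seed: int

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration_s < MIN_TRIAL_DURATION_S:
            raise ValueError(
                f"duration_s must be >= {MIN_TRIAL_DURATION_S} s, got {self.duration_s}"
            )

    @property
    def trial_id(self) -> str:
        return f"{self.subject.subject_id}_{self.activity}_{self.repeat_index}"


@dataclass
class RawTrial:
    """One trial's raw multi-sensor recording.

    ``imu`` has shape (5, T, 9) with channels ordered magnetometer xyz,
    gyroscope xyz (rad/s), accelerometer xyz (m/s^2); ``imu_rotation``
    has shape (5, T, 3, 3); ``audio`` is a mono float waveform at
    44.1 kHz of length 882*T.
    """

    trial_id: str
    subject_id: str
    group: str
    label: str | None
    imu: np.ndarray
    imu_rotation: np.ndarray
    audio: np.ndarray
    calibration: "RawTrial | None" = None
    fs_imu: int = FS_IMU
    fs_audio: int = FS_AUDIO

    @property
    def n_samples(self) -> int:
        return self.imu.shape[1]


def generate_cohort(
    n_patients: int,
    n_controls: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> list[SubjectProfile]:
    """Draw per-subject latent profiles for a patient/control cohort.

    Deterministic under ``seed``: the profile of subject *i* depends only
    on the cohort seed and the subject index.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_patients + n_controls < 2:
        raise ValueError("total cohort size must be at least 2")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    groups = ["patient"] * n_patients + ["control"] * n_controls
    n_digits = max(2, len(str(n_patients + n_controls)))
    p_idx = c_idx = 0
    for group in groups:
        if group == "patient":
            p_idx += 1
            sid = f"P{p_idx:0{n_digits}d}"
            tremor = rng.uniform(*config.tremor_amplitude_range)
            variability = rng.uniform(*config.patient_variability_range)
        else:
            c_idx += 1
            sid = f"C{c_idx:0{n_digits}d}"
            tremor = 0.0
            _ = rng.uniform(*config.tremor_amplitude_range)  # keep draw count aligned
            variability = rng.uniform(*config.control_variability_range)
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                group=group,
                motion_scale=rng.uniform(*config.motion_scale_range),
                tremor_amplitude=tremor,
                variability=variability,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def plan_trials(
    profiles: list[SubjectProfile],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[TrialSpec]:
    """Assign activities, repeats and per-trial seeds for the whole cohort."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    specs = []
    for profile in profiles:
        for activity in ACTIVITIES:
            for rep in range(1, config.n_repeats + 1):
                specs.append(
                    TrialSpec(
                        subject=profile,
                        activity=activity,
                        repeat_index=rep,
                        duration_s=config.trial_duration_s,
                        trial_seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
    return specs


# --------------------------------------------------------------------------
# subject-level latent draws (identical across all trials of a subject)


def _subject_latents(profile: SubjectProfile, config: GeneratorConfig) -> dict:
    rng = np.random.default_rng(profile.rng_seed)
    misalignment = random_rotation(rng, config.misalignment_max_rad)
    latents = {"misalignment": misalignment, "posture_gain": {}, "axis_jitter": {}}
    for stream in IMU_STREAMS:
        # deviation from the canonical posture grows with subject variability
        dev = 0.10 * (profile.variability - 0.6)
        latents["posture_gain"][stream] = float(
            np.clip(1.0 + dev * rng.standard_normal(), 0.4, 1.8)
        )
        jitter = dev * rng.standard_normal(3)
        latents["axis_jitter"][stream] = jitter
    latents["heading"] = rng.uniform(0.0, 2 * np.pi)
    return latents


def _posture_rotvec(
    spec: TrialSpec,
    stream: str,
    t: np.ndarray,
    latents: dict,
    config: GeneratorConfig,
    trial_rng_draws: dict,
) -> np.ndarray:
    """Slow class-specific posture rotation vector, shape (T, 3)."""
    axis, angle = _POSTURE[spec.activity][stream]
    axis = np.asarray(axis, dtype=float)
    axis = axis + latents["axis_jitter"][stream]
    axis = axis / np.linalg.norm(axis)
    # anticipatory posture: partially expressed at inception, then the
    # activity-specific attitude keeps developing over the whole task
    ramp = np.clip(0.3 + 0.7 * t / 14.0, 0.3, 1.0)
    phase = trial_rng_draws["posture_phase"][stream]
    wobble = 1.0 + 0.2 * np.sin(2 * np.pi * 0.7 * t + phase)
    theta = (
        config.contrast
        * angle
        * _STREAM_GAIN[stream]
        * latents["posture_gain"][stream]
        * trial_rng_draws["posture_mult"][stream]
        * ramp
        * wobble
    )
    return axis[None, :] * theta[:, None]


def generate_trial(spec: TrialSpec, config: GeneratorConfig | None = None) -> RawTrial:
    """Synthesise one trial's raw IMU + audio recording.

    Deterministic under ``spec.trial_seed`` (and the subject's
    ``rng_seed`` for subject-level latents).
    """
    config = config or GeneratorConfig()
    if spec.duration_s < MIN_TRIAL_DURATION_S:
        raise ValueError(f"trial duration must be >= {MIN_TRIAL_DURATION_S} s")
    profile = spec.subject
    latents = _subject_latents(profile, config)
    rng = np.random.default_rng(spec.trial_seed)
    T = int(round(spec.duration_s * FS_IMU))
    t = np.arange(T) / FS_IMU

    # trial-level jitters, all scaled by the global noise multiplier; the
    # subject's motor variability scales posture jitter (higher for the
    # patient group), while tremor remains a purely additive component
    amp = profile.tremor_amplitude
    mult_sd = 0.03 * profile.variability
    phase_sd = 0.2 * profile.variability
    draws = {
        "posture_phase": {
            s: config.noise * rng.normal(0.0, phase_sd) for s in IMU_STREAMS
        },
        "posture_mult": {
            s: 1.0 + config.noise * mult_sd * rng.standard_normal()
            for s in IMU_STREAMS
        },
        "osc_phase": {s: config.noise * rng.normal(0.0, 0.8) for s in IMU_STREAMS},
    }
    tremor_freq = rng.uniform(4.0, 6.0)
    tremor_phase = rng.uniform(0.0, 2 * np.pi)
    # orthonormal excitation triad: the amplitude-modulated 4-6 Hz wobble
    # drives all three axes (with decorrelated phases), so tremor adds
    # variance to every channel of every modality
    tremor_dir = rng.standard_normal(3)
    tremor_dir /= np.linalg.norm(tremor_dir)
    aux = rng.standard_normal(3)
    tremor_dir2 = np.cross(tremor_dir, aux)
    tremor_dir2 /= np.linalg.norm(tremor_dir2)
    tremor_dir3 = np.cross(tremor_dir, tremor_dir2)
    tremor_env = 0.6 + 0.4 * np.sin(2 * np.pi * 0.3 * t + tremor_phase)
    tremor_wave = tremor_env * np.sin(2 * np.pi * tremor_freq * t + tremor_phase)
    tremor_wave2 = tremor_env * np.cos(2 * np.pi * tremor_freq * t + tremor_phase)
    tremor_wave3 = tremor_env * np.sin(2 * np.pi * tremor_freq * t + tremor_phase + 1.7)
    tremor_vec = (
        0.8 * (tremor_wave[:, None] * tremor_dir[None, :]
               + tremor_wave2[:, None] * tremor_dir2[None, :])
        + 0.6 * tremor_wave3[:, None] * tremor_dir3[None, :]
    )
    # orientation wobble pairs the waves with different axes so it stays
    # decorrelated from the direct accelerometer/gyro tremor term
    tremor_vec_rot = (
        0.8 * (tremor_wave2[:, None] * tremor_dir[None, :]
               + tremor_wave3[:, None] * tremor_dir2[None, :])
        + 0.6 * tremor_wave[:, None] * tremor_dir3[None, :]
    )

    g_vec = np.array([0.0, 0.0, GRAVITY])
    R0 = latents["misalignment"]
    imu = np.empty((len(IMU_STREAMS), T, 9))
    imu_rot = np.empty((len(IMU_STREAMS), T, 3, 3))
    noise_gain = config.noise * (0.6 + 0.4 * profile.variability)

    for i, stream in enumerate(IMU_STREAMS):
        rv = _posture_rotvec(spec, stream, t, latents, config, draws)
        if amp > 0:
            # tremor shakes the sensor orientation too; the precessing wobble
            # axis reaches every channel of every modality
            rv = rv + (0.1 * amp) * tremor_vec_rot
        P = rotvec_to_matrix(rv)  # (T, 3, 3)
        R_t = np.einsum("ij,tjk->tik", R0, P)
        imu_rot[i] = R_t

        f_base = _BASE_FREQ[stream]
        f_cls = _CLASS_FREQ[spec.activity] + 0.2 * i
        ph = draws["osc_phase"][stream]
        base_osc = profile.motion_scale * np.sin(2 * np.pi * f_base * t + ph)
        cls_osc = config.contrast * _STREAM_GAIN[stream] * np.sin(
            2 * np.pi * f_cls * t + ph
        )

        mag = np.einsum("tij,j->ti", R_t, _MAG_FIELD)
        mag += 0.03 * cls_osc[:, None] * np.array([1.0, -0.5, 0.5])[None, :]
        mag += noise_gain * config.mag_noise_sd * rng.standard_normal((T, 3))

        gyro = np.gradient(rv, 1.0 / FS_IMU, axis=0)
        gyro += (0.5 * base_osc + 0.4 * cls_osc)[:, None] * np.array(
            [0.6, 0.8, 0.2]
        )[None, :]
        if amp > 0:
            gyro += 0.08 * amp * tremor_vec
        gyro += noise_gain * config.gyro_noise_sd * rng.standard_normal((T, 3))

        accel = np.einsum("tij,j->ti", R_t, g_vec)
        accel += (1.2 * base_osc + 1.0 * cls_osc)[:, None] * np.array(
            [0.7, 0.5, 0.3]
        )[None, :]
        if amp > 0:
            accel += amp * tremor_vec
        accel += noise_gain * config.accel_noise_sd * rng.standard_normal((T, 3))

        imu[i] = np.concatenate([mag, gyro, accel], axis=1)

    audio = _generate_audio(spec, config, rng, T)
    return RawTrial(
        trial_id=spec.trial_id,
        subject_id=profile.subject_id,
        group=profile.group,
        label=spec.activity,
        imu=imu,
        imu_rotation=imu_rot,
        audio=audio,
    )


def _click_template(n: int) -> np.ndarray:
    """Deterministic broadband click (fixed pseudo-noise burst)."""
    wave = np.random.default_rng(987654321).standard_normal(n)
    return wave * np.hanning(n)


def _generate_audio(
    spec: TrialSpec, config: GeneratorConfig, rng: np.random.Generator, T: int
) -> np.ndarray:
    n = AUDIO_SAMPLES_PER_IMU_SAMPLE * T
    t_a = np.arange(n) / FS_AUDIO
    audio = np.zeros(n)

    # babble-like conversational background: band-limited Gaussian noise
    if config.noise > 0 and config.babble_level > 0:
        sos = sp_signal.butter(4, [300.0, 3000.0], btype="bandpass", fs=FS_AUDIO, output="sos")
        audio += config.noise * config.babble_level * sp_signal.sosfilt(
            sos, rng.standard_normal(n)
        )

    # faint sustained class tone (e.g. appliance hum)
    tone_hz = _AUDIO_TONE_HZ[spec.activity]
    audio += config.contrast * config.audio_tone_level * np.sin(2 * np.pi * tone_hz * t_a)

    # class-specific event train
    interval = _EVENT_INTERVAL_S[spec.activity]
    event_starts = np.arange(1.0, spec.duration_s - 1.0, interval)
    event_starts = event_starts + config.noise * 0.25 * rng.standard_normal(
        event_starts.shape
    )
    level = config.contrast * config.audio_event_level
    for start in event_starts:
        i0 = int(max(start, 0.0) * FS_AUDIO)
        if spec.activity == "door":  # key-turn-like tone burst
            dur = int(0.18 * FS_AUDIO)
            seg = np.sin(2 * np.pi * 1200.0 * np.arange(dur) / FS_AUDIO)
            seg *= np.hanning(dur)
        elif spec.activity == "cardigan":  # button click
            dur = int(0.06 * FS_AUDIO)
            seg = _click_template(dur)
        else:  # toaster-like buzz with harmonics
            dur = int(0.5 * FS_AUDIO)
            tt = np.arange(dur) / FS_AUDIO
            seg = np.sin(2 * np.pi * 260.0 * tt) + 0.5 * np.sin(2 * np.pi * 520.0 * tt)
            seg *= np.hanning(dur)
        i1 = min(i0 + dur, n)
        if i1 <= i0:
            continue
        gain = level * (1.0 + config.noise * 0.2 * rng.standard_normal())
        audio[i0:i1] += gain * seg[: i1 - i0]
    return audio


def generate_calibration(
    profile: SubjectProfile,
    heading_deg: float = 0.0,
    duration_s: float = 2.0,
    config: GeneratorConfig | None = None,
) -> RawTrial:
    """Static calibration-pose segment (arms by the sides).

    Each stream's orientation is the subject's mounting misalignment
    composed with a yaw by ``heading_deg``; the accelerometer therefore
    reads gravity through that orientation.  The same misalignment is
    embedded in the subject's activity trials, so the calibration
    correction recovers it.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    config = config or GeneratorConfig()
    latents = _subject_latents(profile, config)
    rng = np.random.default_rng(profile.rng_seed + 1)
    T = int(round(duration_s * FS_IMU))
    R = rotation_about_z(np.deg2rad(heading_deg)) @ latents["misalignment"]
    g_vec = np.array([0.0, 0.0, GRAVITY])
    noise_gain = config.noise * (0.6 + 0.4 * profile.variability)
    imu = np.empty((len(IMU_STREAMS), T, 9))
    imu_rot = np.empty((len(IMU_STREAMS), T, 3, 3))
    for i in range(len(IMU_STREAMS)):
        mag = np.tile(R @ _MAG_FIELD, (T, 1))
        mag += noise_gain * config.mag_noise_sd * rng.standard_normal((T, 3))
        gyro = noise_gain * config.gyro_noise_sd * rng.standard_normal((T, 3))
        accel = np.tile(R @ g_vec, (T, 1))
        accel += noise_gain * 0.25 * config.accel_noise_sd * rng.standard_normal((T, 3))
        imu[i] = np.concatenate([mag, gyro, accel], axis=1)
        # small orientation measurement noise, projected back onto SO(3)
        jitter = noise_gain * 0.01 * rng.standard_normal((T, 3))
        imu_rot[i] = np.einsum("ij,tjk->tik", R, rotvec_to_matrix(jitter))
    n_audio = AUDIO_SAMPLES_PER_IMU_SAMPLE * T
    if config.noise > 0 and config.babble_level > 0:
        sos = sp_signal.butter(4, [300.0, 3000.0], btype="bandpass", fs=FS_AUDIO, output="sos")
        audio = config.noise * config.babble_level * sp_signal.sosfilt(
            sos, rng.standard_normal(n_audio)
        )
    else:
        audio = np.zeros(n_audio)
    return RawTrial(
        trial_id=f"{profile.subject_id}_calibration",
        subject_id=profile.subject_id,
        group=profile.group,
        label=None,
        imu=imu,
        imu_rotation=imu_rot,
        audio=audio,
    )


@dataclass
class CohortData:
    """A synthetic cohort: profiles, trial plan and lazy trial generation.

    Trials are regenerated on demand from their seeds rather than held in
    memory (a 21 s trial carries ~1M audio samples).
    """

    profiles: list[SubjectProfile]
    trial_specs: list[TrialSpec]
    config: GeneratorConfig
    seed: int
    _calibrations: dict = field(default_factory=dict, repr=False)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]

    @property
    def groups(self) -> dict[str, str]:
        return {p.subject_id: p.group for p in self.profiles}

    def calibration(self, subject_id: str) -> RawTrial:
        if subject_id not in self._calibrations:
            profile = next(p for p in self.profiles if p.subject_id == subject_id)
            self._calibrations[subject_id] = generate_calibration(
                profile,
                heading_deg=0.0,
                duration_s=self.config.calibration_duration_s,
                config=self.config,
            )
        return self._calibrations[subject_id]

    def iter_trials(self) -> Iterator[RawTrial]:
        for spec in self.trial_specs:
            yield generate_trial(spec, self.config)


def generate_cohort_dataset(
    config: GeneratorConfig | None = None, seed: int = 0
) -> CohortData:
    """Profiles plus a full trial plan for one synthetic cohort."""
    config = config or GeneratorConfig()
    profiles = generate_cohort(config.n_patients, config.n_controls, seed, config)
    specs = plan_trials(profiles, config, seed=seed + 1)
    return CohortData(profiles=profiles, trial_specs=specs, config=config, seed=seed)
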