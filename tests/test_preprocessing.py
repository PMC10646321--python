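"""Calibration correction, heading randomisation, framing, MFCCs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intentsense import GeneratorConfig
from intentsense.config import ALL_SENSORS, AUDIO_SAMPLES_PER_IMU_SAMPLE, FS_AUDIO
from intentsense.preprocessing import (
    Standardizer,
    apply_calibration,
    assemble_streams,
    frame_audio,
    mean_calibration_rotation,
    mfcc_features,
    preprocess_trial,
    random_heading_rotation,
)
from intentsense.rotations import (
    geodesic_distance,
    is_rotation,
    rotation_about_z,
    rotvec_to_matrix,
)
from intentsense.synthetic import generate_calibration, _subject_latents


def _svd_project_oracle(m):
    """Independent nearest-rotation projection (written from the definition)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u2 = u.copy()
        u2[:, -1] *= -1
        r = u2 @ vt
    return r


class TestMeanCalibrationRotation:
    def _make_cal(self, mats, control_calibration):
        cal = control_calibration
        cal.imu_rotation = np.broadcast_to(
            np.stack(mats), (5,) + np.stack(mats).shape
        ).copy()
        return cal

    def test_constant_rotation_recovered_exactly(self, control_calibration):
        R = rotvec_to_matrix(np.array([0.2, -0.1, 0.3]))
        cal = self._make_cal([R, R, R], control_calibration)
        assert np.allclose(mean_calibration_rotation(cal, "imu_ul"), R, atol=1e-12)

    def test_matches_svd_projection_oracle(self, control_calibration):
        R = rotvec_to_matrix(np.array([0.05, 0.02, -0.04]))
        cal = self._make_cal([R, R.T], control_calibration)
        expected = _svd_project_oracle((R + R.T) / 2.0)
        assert np.allclose(mean_calibration_rotation(cal, "imu_ul"), expected, atol=1e-12)

    def test_noisy_samples_recover_reference(self, control_calibration):
        rng = np.random.default_rng(11)
        R0 = rotvec_to_matrix(np.array([0.3, -0.2, 0.1]))
        mats = [
            R0 @ rotvec_to_matrix(rng.normal(0.0, 0.01, size=3)) for _ in range(100)
        ]
        cal = self._make_cal(mats, control_calibration)
        est = mean_calibration_rotation(cal, "imu_ul")
        assert geodesic_distance(est, R0) < 0.05

    def test_empty_calibration_errors(self, control_calibration):
        control_calibration.imu_rotation = control_calibration.imu_rotation[:, :0]
        with pytest.raises(ValueError, match="empty calibration"):
            mean_calibration_rotation(control_calibration, "imu_ul")


class TestApplyCalibration:
    def test_identity_rotations_leave_trial_unchanged(self, control_trial):
        out = apply_calibration(control_trial, {s: np.eye(3) for s in ALL_SENSORS[:5]})
        assert np.allclose(out.imu, control_trial.imu, atol=1e-12)
        assert np.allclose(out.imu_rotation, control_trial.imu_rotation, atol=1e-12)

    def test_rotate_then_calibrate_roundtrip(self, control_trial):
        R = rotvec_to_matrix(np.array([0.4, 0.1, -0.2]))
        rot = {s: R for s in ALL_SENSORS[:5]}
        rotated = apply_calibration(control_trial, {s: R.T for s in ALL_SENSORS[:5]})
        back = apply_calibration(rotated, rot)
        assert np.allclose(back.imu, control_trial.imu, atol=1e-9)

    def test_non_rotation_rejected(self, control_trial):
        bad = {s: np.eye(3) * 2.0 for s in ALL_SENSORS[:5]}
        with pytest.raises(ValueError, match="not a rotation"):
            apply_calibration(control_trial, bad)

    def test_embedded_misalignment_recovered(self, control_profile):
        """Round trip with the generator: correcting the calibration segment
        by its own mean rotation puts gravity back on the vertical axis."""
        cfg = GeneratorConfig(noise=0.0)
        cal = generate_calibration(control_profile, heading_deg=0.0, config=cfg)
        rotations = {s: mean_calibration_rotation(cal, s) for s in ALL_SENSORS[:5]}
        # the embedded misalignment is recovered to within a small angle
        R0 = _subject_latents(control_profile, cfg)["misalignment"]
        for s in ALL_SENSORS[:5]:
            assert geodesic_distance(rotations[s], R0) < 0.05
        corrected = apply_calibration(cal, rotations)
        mean_accel = corrected.imu[:, :, 6:9].mean(axis=1)
        assert np.allclose(mean_accel, [0.0, 0.0, 9.81], atol=1e-2)


class TestHeadingRandomization:
    def test_vertical_components_unchanged_any_seed(self, control_trial):
        for seed in (0, 1, 17):
            out = random_heading_rotation(control_trial, seed=seed)
            for c0 in (0, 3, 6):
                assert np.array_equal(
                    out.imu[:, :, c0 + 2], control_trial.imu[:, :, c0 + 2]
                )

    def test_norms_preserved(self, control_trial):
        out = random_heading_rotation(control_trial, seed=3)
        for c0 in (0, 3, 6):
            n_in = np.linalg.norm(control_trial.imu[:, :, c0 : c0 + 3], axis=2)
            n_out = np.linalg.norm(out.imu[:, :, c0 : c0 + 3], axis=2)
            assert np.allclose(n_in, n_out, atol=1e-9)

    def test_same_angle_for_all_streams(self, control_trial):
        out = random_heading_rotation(control_trial, seed=5)
        # relative rotation of the orientation channel is identical per stream
        rel = np.einsum(
            "stij,stkj->stik", out.imu_rotation, control_trial.imu_rotation
        )
        assert np.allclose(rel, rel[:1], atol=1e-9)

    def test_yaw_half_turn_closed_form(self):
        assert np.allclose(rotation_about_z(np.pi) @ [1, 0, 0], [-1, 0, 0], atol=1e-12)


class TestFrameAudio:
    def test_exact_division(self):
        frames = frame_audio(np.zeros(926_100), 1050)
        assert frames.shape == (1050, 882)

    def test_truncation_rule(self):
        audio = np.arange(1000.0)
        frames = frame_audio(audio, 1)
        assert frames.shape == (1, 882)
        assert np.array_equal(frames[0], audio[:882])

    def test_default_length_floor(self):
        assert frame_audio(np.zeros(2000)).shape == (2, 882)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            frame_audio(np.zeros(500), 1)


def _mfcc_oracle(frame):
    """Independent loop-based MFCC with the documented settings."""
    n = 882
    window = np.hamming(n)
    spectrum = np.fft.rfft(frame * window)
    power = (spectrum.real**2 + spectrum.imag**2) / n
    # mel filterbank, built from scratch
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(0.0), mel(FS_AUDIO / 2.0), 28))
    freqs = np.arange(n // 2 + 1) * FS_AUDIO / n
    energies = np.zeros(26)
    for m in range(26):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        weight = np.zeros_like(freqs)
        rising = (freqs >= lo) & (freqs <= mid)
        falling = (freqs > mid) & (freqs <= hi)
        weight[rising] = (freqs[rising] - lo) / (mid - lo)
        weight[falling] = (hi - freqs[falling]) / (hi - mid)
        energies[m] = np.sum(weight * power)
    log_e = np.log(np.maximum(energies, 1e-10))
    coeffs = np.zeros(18)
    for k in range(18):
        basis = np.cos(np.pi * k * (2 * np.arange(26) + 1) / (2 * 26))
        scale = np.sqrt(1.0 / 26) if k == 0 else np.sqrt(2.0 / 26)
        coeffs[k] = scale * np.sum(log_e * basis)
    return coeffs


class TestMFCC:
    def test_always_18_coefficients(self):
        rng = np.random.default_rng(0)
        out = mfcc_features(rng.normal(size=(7, 882)))
        assert out.features.shape == (7, 18)

    def test_silence_is_finite_constant_pattern(self):
        out = mfcc_features(np.zeros((3, 882)))
        assert np.all(np.isfinite(out.features))
        assert np.allclose(out.features, out.features[0])

    def test_pure_tone_matches_independent_oracle(self):
        t = np.arange(882) / FS_AUDIO
        tone = 0.5 * np.sin(2 * np.pi * 1000.0 * t)
        ours = mfcc_features(tone[None, :]).features[0]
        assert np.allclose(ours, _mfcc_oracle(tone), atol=1e-6)

    def test_frame_aligned_shift_invariance(self):
        rng = np.random.default_rng(4)
        audio = rng.normal(size=882 * 5)
        orig = mfcc_features(frame_audio(audio, 5)).features
        shifted = mfcc_features(frame_audio(np.concatenate([np.zeros(882), audio]), 6)).features
        assert np.allclose(shifted[1:], orig[:5], atol=1e-12)


class TestAssembly:
    def test_six_streams_108_features(self, control_trial):
        streams = assemble_streams(control_trial)
        assert set(streams) == set(ALL_SENSORS)
        assert sum(s.features.shape[1] for s in streams.values()) == 108
        lengths = {s.features.shape[0] for s in streams.values()}
        assert lengths == {control_trial.n_samples}

    def test_full_chain_produces_aligned_features(self, control_trial, control_calibration):
        tf = preprocess_trial(control_trial, control_calibration, heading_seed=3)
        assert tf.as_array().shape == (control_trial.n_samples, 6, 18)

    def test_standardizer_constant_feature_and_leakage_contract(
        self, control_trial, control_calibration
    ):
        tf = preprocess_trial(control_trial, control_calibration, heading_seed=3)
        tf.streams["audio"].features[:, 0] = 5.0  # constant feature
        std = Standardizer().fit([tf])
        out = std.transform(tf)
        assert np.allclose(out.streams["audio"].features[:, 0], 0.0)
        # a different trial is transformed with the training statistics
        tf2 = preprocess_trial(control_trial, control_calibration, heading_seed=4)
        out2 = std.transform(tf2)
        expected = (tf2.streams["imu_ul"].features - std.mean_["imu_ul"]) / std.scale_[
            "imu_ul"
        ]
        assert np.allclose(out2.streams["imu_ul"].features, expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3))
def test_rotvec_matrices_are_rotations_and_preserve_norm(rv):
    R = rotvec_to_matrix(np.array(rv))
    assert is_rotation(R, tol=1e-9)
    v = np.array([0.3, -1.2, 2.0])
    assert np.isclose(np.linalg.norm(R @ v), np.linalg.norm(v), atol=1e-9)
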