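"""Small rotation-matrix helpers shared by the generator and preprocessing.

Convention: right-handed global frame with Z up; the accelerometer reads
+9.81 m/s^2 along global Z in the static calibration pose.
"""

from __future__ import annotations

import numpy as np

GRAVITY = 9.81  #: m/s^2, +Z in the global frame

__all__ = [
    "GRAVITY",
    "is_rotation",
    "project_to_rotation",
    "rotation_about_z",
    "random_rotation",
    "rotvec_to_matrix",
    "geodesic_distance",
]


def is_rotation(matrix: np.ndarray, tol: float = 1e-6) -> bool:
    """True if ``matrix`` is orthogonal with determinant +1 within ``tol``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        return False
    if not np.allclose(matrix.T @ matrix, np.eye(3), atol=tol):
        return False
    return bool(abs(np.linalg.det(matrix) - 1.0) <= tol)


def project_to_rotation(matrix: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix in the Frobenius sense, via SVD.

    The determinant is forced to +1, so reflections are projected onto
    proper rotations. Raises ``np.linalg.LinAlgError`` style failure for
    rank-deficient input (singular values below 1e-12).
    """
    matrix = np.asarray(matrix, dtype=float)
    u, s, vt = np.linalg.svd(matrix)
    if np.min(s) < 1e-12:
        raise np.linalg.LinAlgError(
            "mean rotation matrix is numerically rank-deficient "
            f"(singular values {s}); cannot project onto SO(3)"
        )
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def rotation_about_z(angle_rad: float) -> np.ndarray:
    """Yaw rotation about the global vertical (Z) axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues formula for a stack of rotation vectors (..., 3) -> (..., 3, 3)."""
    rotvec = np.asarray(rotvec, dtype=float)
    theta = np.linalg.norm(rotvec, axis=-1, keepdims=True)
    small = theta < 1e-12
    axis = np.where(small, 0.0, rotvec / np.where(small, 1.0, theta))
    theta = theta[..., 0]
    k = np.zeros(rotvec.shape[:-1] + (3, 3))
    k[..., 0, 1] = -axis[..., 2]
    k[..., 0, 2] = axis[..., 1]
    k[..., 1, 0] = axis[..., 2]
    k[..., 1, 2] = -axis[..., 0]
    k[..., 2, 0] = -axis[..., 1]
    k[..., 2, 1] = axis[..., 0]
    sin_t = np.sin(theta)[..., None, None]
    cos_t = np.cos(theta)[..., None, None]
    eye = np.broadcast_to(np.eye(3), k.shape)
    return eye + sin_t * k + (1.0 - cos_t) * (k @ k)


def random_rotation(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    """Rotation about a uniformly random axis, angle uniform on [0, max_angle_rad]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_rad)
    return rotvec_to_matrix(axis * angle)


def geodesic_distance(r1: np.ndarray, r2: np.ndarray) -> float:
    """Angle in radians of the relative rotation ``r1.T @ r2``."""
    rel = np.asarray(r1).T @ np.asarray(r2)
    cos_angle = np.clip((np.trace(rel) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.arccos(cos_angle))
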