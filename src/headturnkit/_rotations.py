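"""Small rotation-matrix helpers shared by the generator and the alignment code.

Conventions used throughout the package:

* segment frame axes are (AP, ML, V) with V pointing up;
* a resting accelerometer reads ``(0, 0, -1)`` g in the segment frame;
* a mounting rotation ``C`` maps segment-frame vectors into sensor-frame
  vectors (``v_sensor = C @ v_segment``), so a perfect alignment recovers
  ``R = C.T`` with ``v_segment = R @ v_sensor``.
"""

from __future__ import annotations

import numpy as np


def rot_x(deg: float) -> np.ndarray:
    """Rotation about the AP (x) axis."""
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    """Rotation about the ML (y) axis."""
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    """Rotation about the vertical (z) axis."""
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def euler_zyx(z_deg: float, y_deg: float, x_deg: float) -> np.ndarray:
    """Intrinsic Z-Y-X Euler rotation (degrees): R = Rz @ Ry @ Rx."""
    return rot_z(z_deg) @ rot_y(y_deg) @ rot_x(x_deg)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal (Rodrigues) rotation mapping unit vector ``u`` onto unit vector ``v``."""
    u = np.asarray(u, dtype=float) / np.linalg.norm(u)
    v = np.asarray(v, dtype=float) / np.linalg.norm(v)
    w = np.cross(u, v)
    c = float(np.dot(u, v))
    if np.linalg.norm(w) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate 180 degrees about any axis orthogonal to u
        a = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, a)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )
    return np.eye(3) + K + K @ K / (1.0 + c)


def is_proper_rotation(R: np.ndarray, atol: float = 1e-9) -> bool:
    """True when R is orthonormal with determinant +1 (within atol)."""
    return bool(
        np.allclose(R.T @ R, np.eye(3), atol=atol)
        and abs(np.linalg.det(R) - 1.0) <= atol
    )
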