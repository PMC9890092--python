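"""Rigid-transform helpers on plain 4x4 numpy arrays.

Conventions: right-handed frames, +x anterior, +y dorsal, +z lateral (right
side). Transforms map local coordinates to parent/world coordinates:
``p_world = T @ [p_local, 1]``.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.eye(4)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def make_transform(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = np.asarray(rotation, dtype=float)
    T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def translation_matrix(t: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = np.asarray(t, dtype=float)
    return T


def rotation_part(T: np.ndarray) -> np.ndarray:
    return T[:3, :3]


def transform_point(T: np.ndarray, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return T[:3, :3] @ p + T[:3, 3]


def transform_direction(T: np.ndarray, d: np.ndarray) -> np.ndarray:
    return T[:3, :3] @ np.asarray(d, dtype=float)


def invert(T: np.ndarray) -> np.ndarray:
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def rotation_about_line(point: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """4x4 rotation about the line through ``point`` with direction ``axis``."""
    R = rotation_about_axis(axis, angle_rad)
    point = np.asarray(point, dtype=float)
    return make_transform(R, point - R @ point)


def is_proper_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        return False
    return abs(np.linalg.det(R) - 1.0) <= tol


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return v / n
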