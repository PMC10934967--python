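"""3-D rotations shared by the cohort generator and the augmentation stage."""

from __future__ import annotations

import numpy as np


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues).

    ``axis`` need not be normalized; a zero axis is rejected.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be a non-zero vector")
    k = axis / norm
    theta = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rotate_columns(signal: np.ndarray, cols: tuple[int, int, int], R: np.ndarray) -> None:
    """Rotate, in place, the 3-vector formed by ``cols`` at every time point."""
    signal[:, cols] = signal[:, cols] @ R.T
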