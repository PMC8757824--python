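"""Vectorized quaternion/rotation kernels for the solver hot loop.

Quaternions are scalar-last (x, y, z, w), matching scipy's convention.
"""

from __future__ import annotations

import numpy as np


def quat_to_mat(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    n = x * x + y * y + z * z + w * w
    s = 2.0 / n
    xx, yy, zz = x * x * s, y * y * s, z * z * s
    xy, xz, yz = x * y * s, x * z * s, y * z * s
    wx, wy, wz = w * x * s, w * y * s, w * z * s
    M = np.empty(q.shape[:-1] + (3, 3))
    M[..., 0, 0] = 1.0 - (yy + zz)
    M[..., 0, 1] = xy - wz
    M[..., 0, 2] = xz + wy
    M[..., 1, 0] = xy + wz
    M[..., 1, 1] = 1.0 - (xx + zz)
    M[..., 1, 2] = yz - wx
    M[..., 2, 0] = xz - wy
    M[..., 2, 1] = yz + wx
    M[..., 2, 2] = 1.0 - (xx + yy)
    return M


def mat_to_rotvec(M: np.ndarray) -> np.ndarray:
    """Rotation vector of rotation matrices (vectorized log map).

    Accurate for angles up to pi - eps; the corotational local rotations it
    is applied to stay well below that.
    """
    tr = M[..., 0, 0] + M[..., 1, 1] + M[..., 2, 2]
    c = np.clip((tr - 1.0) * 0.5, -1.0, 1.0)
    theta = np.arccos(c)
    ax = np.stack(
        [
            M[..., 2, 1] - M[..., 1, 2],
            M[..., 0, 2] - M[..., 2, 0],
            M[..., 1, 0] - M[..., 0, 1],
        ],
        axis=-1,
    )
    s = np.sin(theta)
    # theta/(2 sin theta), series-expanded near zero
    small = s < 1e-6
    factor = np.empty_like(theta)
    factor[~small] = theta[~small] / (2.0 * s[~small])
    t2 = theta[small] * theta[small]
    factor[small] = 0.5 + t2 / 12.0 + 7.0 * t2 * t2 / 720.0
    return ax * factor[..., None]


def rotvec_to_quat(rv: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(rv, axis=-1)
    half = 0.5 * angle
    small = angle < 1e-12
    k = np.empty_like(angle)
    k[~small] = np.sin(half[~small]) / angle[~small]
    k[small] = 0.5
    q = np.empty(rv.shape[:-1] + (4,))
    q[..., :3] = rv * k[..., None]
    q[..., 3] = np.cos(half)
    return q


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b (apply b first, then a), scalar-last."""
    ax, ay, az, aw = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bx, by, bz, bw = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    q = np.empty(np.broadcast(a, b).shape)
    q[..., 0] = aw * bx + ax * bw + ay * bz - az * by
    q[..., 1] = aw * by - ax * bz + ay * bw + az * bx
    q[..., 2] = aw * bz + ax * by - ay * bx + az * bw
    q[..., 3] = aw * bw - ax * bx - ay * by - az * bz
    return q


def normalize_quat(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
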