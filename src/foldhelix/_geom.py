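"""Small vectorized geometry helpers shared across the analysis modules.

Angles are degrees at module boundaries and radians internally, following
the package-wide convention.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; zero vectors map to nan."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / n


def wrap_deg(a):
    """Wrap angles in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Planar angle between corresponding vectors, degrees in [0, 180].

    Uses atan2(|u x v|, u.v), which keeps full precision for nearly
    parallel vectors where arccos loses ~8 digits.
    """
    un, vn = unit(u), unit(v)
    cross = np.linalg.norm(np.cross(un, vn), axis=-1)
    dot = np.sum(un * vn, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def dihedral_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, (-180, 180].

    Standard IUPAC sign convention, computed fully in float64 (library
    dihedral kernels typically work in single precision, which is not
    enough for the exactness contracts on ideal geometries). Accepts
    arrays of shape (..., 3). Degenerate (collinear) quadruples yield NaN.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = -np.sum(m1 * n2, axis=-1)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(y, x))
        bad = (np.sum(n1 * n1, axis=-1) < 1e-18) | (np.sum(n2 * n2, axis=-1) < 1e-18)
    return np.where(bad, np.nan, wrap_deg(ang))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` (Rodrigues), right-handed."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrices mapping unit vectors ``a`` onto ``b`` about a x b.

    Vectorized over leading dimensions; returns (..., 3, 3). For nearly
    parallel inputs the identity is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    v = np.cross(a, b)
    c = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    s2 = np.sum(v * v, axis=-1)
    eye = np.broadcast_to(np.eye(3), a.shape[:-1] + (3, 3)).copy()
    # skew-symmetric cross-product matrices
    K = np.zeros(a.shape[:-1] + (3, 3))
    K[..., 0, 1] = -v[..., 2]
    K[..., 0, 2] = v[..., 1]
    K[..., 1, 0] = v[..., 2]
    K[..., 1, 2] = -v[..., 0]
    K[..., 2, 0] = -v[..., 1]
    K[..., 2, 1] = v[..., 0]
    ok = s2 > 1e-24
    factor = np.where(ok, (1.0 - c) / np.where(ok, s2, 1.0), 0.0)
    R = eye + K + factor[..., None, None] * (K @ K)
    return R


def rotate_points_about_line(points, origin, axis, angle_deg):
    """Rotate points (..., 3) about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    p = np.asarray(points, dtype=float) - origin
    return p @ R.T + origin


def kabsch_align(mobile: np.ndarray, ref: np.ndarray):
    """Optimal (least-squares) superposition of ``mobile`` onto ``ref``.

    Returns the transformed coordinates. Both inputs are (N, 3).
    """
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return mc @ R + ref.mean(axis=0)
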