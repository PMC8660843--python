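"""Low-level geometric primitives: torsions, superposition, chain building.

Torsion sign follows the IUPAC right-hand rule: looking down the central
bond b->c, the angle is positive when the far bond c->d is rotated
clockwise relative to a->b.  Values are reported in (-pi, pi].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "torsion",
    "wrap_angle",
    "kabsch_rotation",
    "superpose",
    "nerf_place",
    "rotation_about_axis",
]


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (radians) into (-pi, pi]; -pi maps to +pi."""
    wrapped = np.remainder(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(theta):
        return float(wrapped)
    return wrapped


def torsion(a, b, c, d) -> np.ndarray:
    """Torsion angle (radians) of four points, vectorized over leading axes.

    Parameters are arrays broadcastable to (..., 3).  Returns angles in
    (-pi, pi]; NaN where the three bond vectors are degenerate (collinear
    central atoms).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.cross(n1, n2)
        y = np.sum(m1 * b2, axis=-1) / np.where(b2n == 0.0, np.nan, b2n)
        x = np.sum(n1 * n2, axis=-1)
        ang = np.arctan2(y, x)
    # degenerate: either normal vanishes (collinear triples)
    bad = (np.linalg.norm(n1, axis=-1) < 1e-12) | (np.linalg.norm(n2, axis=-1) < 1e-12)
    ang = np.where(bad, np.nan, ang)
    return wrap_angle(ang)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray, weights=None) -> np.ndarray:
    """Optimal rotation matrix aligning centered `mobile` onto centered `target`."""
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, dtype=float)[:, None]
    h = (mobile * w).T @ target
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, sign])
    return vt.T @ diag @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray, weights=None) -> np.ndarray:
    """Weighted least-squares superposition of one frame onto a target."""
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cm = (mobile * w[:, None]).sum(axis=0)
    ct = (target * w[:, None]).sum(axis=0)
    rot = kabsch_rotation(mobile - cm, target - ct, w)
    return (mobile - cm) @ rot.T + ct


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, right-handed."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    one_c = 1.0 - c
    return np.array(
        [
            [c + x * x * one_c, x * y * one_c - z * s, x * z * one_c + y * s],
            [y * x * one_c + z * s, c + y * y * one_c, y * z * one_c - x * s],
            [z * x * one_c - y * s, z * y * one_c + x * s, c + z * z * one_c],
        ]
    )


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_rad, torsion_rad) -> np.ndarray:
    """Place atom D from reference atoms A, B, C with internal coordinates.

    D is bonded to C at distance `bond`, with bond angle B-C-D `angle_rad`
    and torsion A-B-C-D `torsion_rad` under the same sign convention as
    :func:`torsion` (natural extension frame, standard NeRF construction).
    Broadcasts over leading axes: a/b/c of shape (..., 3) and scalar or
    (...)-shaped angles place one atom per leading entry.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    angle_rad = np.asarray(angle_rad, dtype=float)
    torsion_rad = np.asarray(torsion_rad, dtype=float)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n_hat, bc_hat)
    d0 = -bond * np.cos(angle_rad)
    d1 = bond * np.sin(angle_rad) * np.cos(torsion_rad)
    d2 = bond * np.sin(angle_rad) * np.sin(torsion_rad)
    return c + (bc_hat * d0[..., None] + m * d1[..., None] + n_hat * d2[..., None])
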