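"""Low-level rigid-body and internal-coordinate geometry helpers.

All angles are in degrees at the public interface, coordinates in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "rot_z",
    "tilt_rotation",
    "kabsch",
    "superpose",
    "rmsd",
    "nerf_place",
    "principal_axis",
    "dihedral",
]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def rot_z(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def tilt_rotation(tilt_deg: float, tilt_azimuth_deg: float) -> np.ndarray:
    """Rotation taking +z to a direction tilted by ``tilt_deg`` toward the
    azimuth ``tilt_azimuth_deg`` in the xy-plane (R_z(az) R_y(tilt) R_z(-az))."""
    az = rot_z(tilt_azimuth_deg)
    a = np.deg2rad(tilt_deg)
    c, s = np.cos(a), np.sin(a)
    ry = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return az @ ry @ az.T


def kabsch(mobile: np.ndarray, target: np.ndarray, weights=None):
    """Optimal rotation/translation mapping ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the weighted
    RMSD to ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"coordinate sets differ in shape: {mobile.shape} vs {target.shape}"
        )
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cm = w @ mobile
    ct = w @ target
    h = (mobile - cm).T @ ((target - ct) * w[:, None])
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - r @ cm
    return r, t


def superpose(mobile_fit, target_fit, mobile_all):
    """Superpose ``mobile_all`` using the fit computed on the fit sets."""
    r, t = kabsch(mobile_fit, target_fit)
    return np.asarray(mobile_all, dtype=float) @ r.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom D given three reference atoms (natural extension reference
    frame): ``|C-D| = bond``, ``angle(B,C,D) = angle_deg``,
    ``dihedral(A,B,C,D) = torsion_deg``."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return c + m @ d_local


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal component of a coordinate cloud (unit vector; sign is
    arbitrary and must be fixed by the caller)."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))
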