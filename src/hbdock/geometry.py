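"""Small vector-geometry helpers used throughout the package.

All coordinates are Cartesian, in Angstrom; all angles are in degrees.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Unit vector along ``v``; raises on (near-)zero input."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Interior angle a-b-c at vertex ``b``."""
    u, w = unit(np.asarray(a) - b), unit(np.asarray(c) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in (-180, 180]."""
    b1 = np.asarray(p2) - p1
    b2 = np.asarray(p3) - p2
    b3 = np.asarray(p4) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = -np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_internal(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position a fourth atom D from internal coordinates.

    D is placed at distance ``bond`` from ``c``, with angle D-c-b equal to
    ``angle`` and torsion D-c-b-a equal to ``dihedral`` (NeRF construction).
    """
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    theta = np.radians(angle)
    phi = np.radians(dihedral)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    return Rotation.from_rotvec(np.radians(angle_degrees) * unit(np.asarray(axis, float))).as_matrix()


def rotate_about_bond(coords: np.ndarray, p_from: np.ndarray, p_to: np.ndarray,
                      angle_degrees: float) -> np.ndarray:
    """Rotate ``coords`` about the axis through p_from -> p_to."""
    R = rotation_about_axis(np.asarray(p_to) - p_from, angle_degrees)
    return (coords - p_from) @ R.T + p_from


def superpose_points(fixed: np.ndarray, moving: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` such that ``moving @ R.T + t`` best fits
    ``fixed``.  The rotation is always proper (det = +1).
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - cf, moving - cm)
    R = rot.as_matrix()
    t = cf - cm @ R.T
    rmsd = float(rssd) / np.sqrt(len(fixed))
    return R, t, rmsd
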