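"""Small 3-D geometry helpers.

Rotations about arbitrary axes (the primitive behind forward kinematics) and
internal-coordinate atom placement (the primitive behind the synthetic
structure builders).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Return v / |v|; raises on a zero vector."""
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """3x3 right-handed rotation by `angle` (radians) about unit vector `axis`."""
    return Rotation.from_rotvec(np.asarray(axis, dtype=float) * angle).as_matrix()


def rotation_about_line(point: np.ndarray, axis: np.ndarray, angle: float):
    """Affine rotation about the line through `point` along unit `axis`.

    Returns (R, t) such that x -> R @ x + t.
    """
    R = rotation_about_axis(axis, angle)
    t = point - R @ point
    return R, t


def compose(Ra, ta, Rb, tb):
    """Compose affine maps: (Ra, ta) o (Rb, tb), i.e. apply b first."""
    return Ra @ Rb, Ra @ tb + ta


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def angle_between(v1, v2) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    c = np.dot(unit(np.asarray(v1, float)), unit(np.asarray(v2, float)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom bonded to `c` from internal coordinates.

    `length` is the c-new bond length, `angle_deg` the b-c-new angle and
    `torsion_deg` the a-b-c-new dihedral (natural extension / NeRF scheme).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(angle_deg)
    chi = -np.radians(torsion_deg)  # so dihedral(a, b, c, new) == torsion_deg
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * np.cos(th),
            length * np.sin(th) * np.cos(chi),
            length * np.sin(th) * np.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n
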