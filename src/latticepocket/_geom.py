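"""Low-level 3D geometry: dihedral angles and internal-coordinate placement."""

from __future__ import annotations

import math

import numpy as np


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d so that |c-d| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = dihedral_deg (natural-extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m - d_local[2] * n


def rotation_aligning(v, w) -> np.ndarray:
    """Rotation matrix taking unit direction of v onto unit direction of w."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    c = float(np.dot(v, w))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to v for the half-turn
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return rotation_about(axis, 180.0)
    axis = np.cross(v, w)
    s = np.linalg.norm(axis)
    axis = axis / s
    return rotation_about(axis, math.degrees(math.atan2(s, c)))


def rotation_about(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)
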