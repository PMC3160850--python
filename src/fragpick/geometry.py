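"""Small rigid-body geometry toolkit: torsions, atom placement, superposition.

All angles at this interface are in degrees; torsions follow the standard
signed convention and live in (-180, 180].
"""
from __future__ import annotations

import numpy as np


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees) defined by four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom D given atoms A, B, C with |CD|=bond, angle(BCD) and
    torsion(ABCD).  The NeRF internal-to-Cartesian step."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between two point sets over all rigid superpositions.

    Uses the Kabsch SVD algorithm with the determinant sign correction for
    proper rotations.  ``x`` and ``y`` are (N, 3) arrays in matching order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"point sets must share an (N, 3) shape, got {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s_corr = s.copy()
    s_corr[-1] *= d
    # E = sum|x|^2 + sum|y|^2 - 2 * trace(Sigma)
    e0 = (xc ** 2).sum() + (yc ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * s_corr.sum()) / x.shape[0])
    return float(np.sqrt(msd))


def wrapped_angular_difference(a_deg: float, b_deg: float) -> float:
    """Absolute difference of two angles on the circle, in degrees, <= 180."""
    d = (a_deg - b_deg) % 360.0
    if d > 180.0:
        d = 360.0 - d
    return abs(d)
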