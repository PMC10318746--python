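"""Small 3-D geometry kernel: internal coordinates, rotations, NeRF atom placement.

Everything operates on plain ``numpy`` arrays in Angstroms / radians.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "bond_angle",
    "dihedral",
    "rotation_about_axis",
    "place_atom",
    "tetrahedral_completions",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u, w = unit(a - b), unit(c - b)
    return float(np.arccos(np.clip(u @ w, -1.0, 1.0)))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in radians, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    k = unit(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """NeRF placement: position D with |C-D| = bond_length, angle(B,C,D) = angle
    and dihedral(A,B,C,D) = torsion (angles in radians)."""
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def tetrahedral_completions(center: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Given a tetrahedral center with two known substituent positions, return the
    two remaining ideal substituent *directions* (unit vectors)."""
    e1, e2 = unit(n1 - center), unit(n2 - center)
    u = unit(e1 + e2)
    w = unit(np.cross(e1, e2))
    beta = 0.5 * np.arccos(-1.0 / 3.0)  # half the tetrahedral angle
    d1 = -u * np.cos(beta) + w * np.sin(beta)
    d2 = -u * np.cos(beta) - w * np.sin(beta)
    return d1, d2
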