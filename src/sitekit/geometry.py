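"""Small vector-geometry helpers: rotations, dihedrals, internal-coordinate
placement.

All coordinates are in nm and all angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "rotation_about_axis",
    "dihedral",
    "place_atom",
    "perpendicular_unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalise ``v`` to unit length; raises on a zero vector."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``.

    Rodrigues' formula; positive angles rotate counter-clockwise when the
    axis points toward the viewer.
    """
    k = unit(axis)
    t = np.deg2rad(angle_deg)
    kx = np.array(
        [[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]]
    )
    return np.eye(3) + np.sin(t) * kx + (1.0 - np.cos(t)) * (kx @ kx)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points.

    The angle is measured about the p1-p2 bond using the standard
    convention: 0 corresponds to a cis (eclipsed) arrangement of p0 and p3.
    Raises ``ValueError`` when either bonded triple is collinear, which
    leaves the torsion undefined.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate (collinear) geometry: dihedral undefined")
    b1u = unit(b1)
    m1 = np.cross(n1, b1u)
    x = n1 @ n2
    y = m1 @ n2
    return float(np.rad2deg(np.arctan2(y, x)))


def place_atom(p0, p1, p2, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a fourth atom from three predecessors and internal coordinates.

    Natural-extension (NeRF) construction: the new atom lies at distance
    ``bond`` from ``p2``, forming the angle ``angle_deg`` at ``p2`` with the
    p1-p2 bond, and the torsion ``dihedral_deg`` about p1-p2 relative to p0.
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    t_ang = np.deg2rad(angle_deg)
    t_dih = np.deg2rad(dihedral_deg)
    d = np.array(
        [
            -bond * np.cos(t_ang),
            bond * np.sin(t_ang) * np.cos(t_dih),
            bond * np.sin(t_ang) * np.sin(t_dih),
        ]
    )
    bc = unit(p2 - p1)
    n = unit(np.cross(p1 - p0, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return p2 + m @ d


def perpendicular_unit(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Unit projection of ``v`` onto the plane perpendicular to ``axis``."""
    z = unit(axis)
    w = np.asarray(v, dtype=float) - (np.asarray(v, dtype=float) @ z) * z
    return unit(w)
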