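"""Internal-coordinate geometry: atom placement (NeRF), torsion measurement, rotations.

Scalar math is used in the placement hot path on purpose: building a chain is a
sequential loop over atoms, and per-atom numpy calls would dominate runtime.
"""

from __future__ import annotations

import math

import numpy as np

Vec3 = tuple[float, float, float]


def place_atom(a: Vec3, b: Vec3, c: Vec3, bond: float, angle_deg: float,
               torsion_deg: float) -> Vec3:
    """Position atom d with |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural extension reference frame)."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    n = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / n, bcy / n, bcz / n

    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    # n_u = unit(ab x bc)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m_u = n_u x bc_u
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx

    d0 = -bond * math.cos(theta)
    d1 = bond * math.sin(theta) * math.cos(phi)
    d2 = bond * math.sin(theta) * math.sin(phi)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def wrap_angle(deg: float) -> float:
    """Wrap an angle difference to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a <= -180.0 else a


def rotation_about_axis(point: np.ndarray, axis_unit: np.ndarray,
                        angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (R, t) so that x -> R @ x + t rotates about the axis through `point`."""
    th = math.radians(angle_deg)
    ux, uy, uz = axis_unit
    c, s = math.cos(th), math.sin(th)
    C = 1.0 - c
    R = np.array([
        [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
        [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
        [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
    ])
    t = point - R @ point
    return R, t
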