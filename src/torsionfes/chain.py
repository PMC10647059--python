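"""Cartesian realization of a minimal five-atom side-chain fragment.

Given a (chi1, chi2) series, this module builds per-frame 3D coordinates
for the atoms N, CA, CB, CG, CD1 of a tryptophan-like fragment by standard
internal-to-Cartesian placement (the natural-extension reference frame):
bond lengths and bond angles are held fixed across frames and only the two
torsions vary, so torsion extraction from the written coordinates must
reproduce the requested series exactly (to within floating-point noise,
well below 1e-6 degrees).

The geometry values are arbitrary but fixed -- the analysis depends only
on torsions, never on bond lengths or angles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import AngleSeries
from .torsion import GeometryError
from .trajio import Trajectory

__all__ = ["ChainGeometry", "realize_coordinates", "ATOM_NAMES"]

ATOM_NAMES = ["N", "CA", "CB", "CG", "CD1"]


@dataclass(frozen=True)
class ChainGeometry:
    """Fixed internal coordinates of the fragment.

    bond_length : every bond, angstrom.
    bond_angle : every bond angle, degrees; must be strictly inside (0, 180).
    """

    bond_length: float = 1.5
    bond_angle: float = 111.0

    def __post_init__(self):
        if self.bond_length <= 0:
            raise GeometryError(f"bond length must be > 0, got {self.bond_length}")
        if not 0.0 < self.bond_angle < 180.0:
            raise GeometryError(
                f"bond angle {self.bond_angle} deg is degenerate "
                f"(collinear atoms have no defined torsion)")


def _place(a, b, c, r, theta_deg, phi_deg):
    """Position atom D so |CD| = r, angle(B,C,D) = theta, torsion(A,B,C,D) = phi.

    Vectorized over leading frame dimensions of phi_deg.
    """
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise GeometryError("collinear reference atoms in internal-coordinate placement")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    local = np.stack([
        np.broadcast_to(-r * np.cos(theta), phi.shape),
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
    ], axis=-1)
    frame = np.stack([bc_hat, m_hat, n_hat], axis=0)  # rows are basis vectors
    return c + local @ frame


def realize_coordinates(
    series: AngleSeries,
    geometry: ChainGeometry = ChainGeometry(),
) -> Trajectory:
    """Build a coordinate trajectory whose chi1/chi2 equal the given series.

    The first three atoms (N, CA, CB) are identical in every frame; CG and
    CD1 are placed from the per-frame torsions.  Round-tripping through
    :func:`torsionfes.torsion.extract_series` recovers the input series to
    better than 1e-6 degrees.
    """
    r = geometry.bond_length
    theta = np.deg2rad(geometry.bond_angle)
    n_pos = np.zeros(3)
    ca_pos = np.array([r, 0.0, 0.0])
    cb_pos = ca_pos + r * np.array([-np.cos(theta), np.sin(theta), 0.0])

    n_frames = len(series)
    cg = _place(n_pos, ca_pos, cb_pos, r, geometry.bond_angle, series.chi1)
    coords = np.empty((n_frames, 5, 3))
    coords[:, 0] = n_pos
    coords[:, 1] = ca_pos
    coords[:, 2] = cb_pos
    coords[:, 3] = cg
    for f in range(n_frames):
        coords[f, 4] = _place(ca_pos, cb_pos, cg[f], r, geometry.bond_angle,
                              series.chi2[f])
    return Trajectory(coords, ATOM_NAMES, [1] * 5, ["TRP"] * 5)
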