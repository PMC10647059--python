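"""Signed dihedral angles and chi1/chi2 time-series extraction.

chi1 is the side-chain torsion over N-CA-CB-CG and chi2 the torsion over
CA-CB-CG-CD1 of a tryptophan-like fragment; both are the collective
variables on which the free-energy surface is built.  The sign follows the
IUPAC convention (cis = 0 degrees; positive for a clockwise rotation of the
far atom viewed along the central bond) and results are wrapped onto
[-180, 180).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .angles import AngleSeries, wrap_angle

if TYPE_CHECKING:  # pragma: no cover
    from .trajio import Trajectory

__all__ = ["GeometryError", "TorsionSpec", "CHI1", "CHI2",
           "compute_dihedral", "extract_series"]

#: Cross products with norm below this (in squared-angstrom units) mark a
#: collinear atom triple, for which the torsion is undefined.
COLLINEARITY_TOL = 1e-10


class GeometryError(ValueError):
    """Raised when a dihedral is requested for degenerate geometry."""


@dataclass(frozen=True)
class TorsionSpec:
    """A named torsion defined by an ordered quadruplet of atom identifiers."""

    name: str
    atoms: tuple[str, str, str, str]

    def __post_init__(self):
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ValueError(f"torsion {self.name!r} needs four distinct atoms, "
                             f"got {self.atoms}")


#: Default side-chain torsion definitions.
CHI1 = TorsionSpec("chi1", ("N", "CA", "CB", "CG"))
CHI2 = TorsionSpec("chi2", ("CA", "CB", "CG", "CD1"))


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees on [-180, 180).

    Uses the atan2 formulation, which is numerically stable for torsions
    near +-90 degrees where an acos-based formula loses precision.

    Vectorized: each argument may be a single 3-point or an (n, 3) stack,
    in which case an array of n angles is returned.

    Raises
    ------
    GeometryError
        if either atom triple (p1,p2,p3) or (p2,p3,p4) is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=-1)
    n2_norm = np.linalg.norm(n2, axis=-1)
    bad = (n1_norm < COLLINEARITY_TOL) | (n2_norm < COLLINEARITY_TOL)
    if np.any(bad):
        frame = int(np.argmax(np.atleast_1d(bad)))
        raise GeometryError(
            f"collinear atom triple (cross-product norm < {COLLINEARITY_TOL:g}) "
            f"at frame {frame}; torsion undefined")
    b2_hat = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2_hat, axis=-1)
    angle = np.degrees(np.arctan2(y, x))
    wrapped = wrap_angle(angle)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def extract_series(
    trajectory: "Trajectory",
    chi1_spec: TorsionSpec = CHI1,
    chi2_spec: TorsionSpec = CHI2,
) -> AngleSeries:
    """Extract the (chi1, chi2) time series from a coordinate trajectory.

    Atom identifiers in the specs are resolved against the trajectory's
    labels (atom name, optionally qualified as ``resseq:name``); an
    unresolvable or ambiguous identifier raises a ``KeyError`` naming it.
    Returns one angle pair per frame, in frame order.
    """
    idx1 = [trajectory.index_of(a) for a in chi1_spec.atoms]
    idx2 = [trajectory.index_of(a) for a in chi2_spec.atoms]
    coords = trajectory.coordinates
    chi1 = compute_dihedral(coords[:, idx1[0]], coords[:, idx1[1]],
                            coords[:, idx1[2]], coords[:, idx1[3]])
    chi2 = compute_dihedral(coords[:, idx2[0]], coords[:, idx2[1]],
                            coords[:, idx2[2]], coords[:, idx2[3]])
    values = np.column_stack([np.atleast_1d(chi1), np.atleast_1d(chi2)])
    return AngleSeries(values, names=(chi1_spec.name, chi2_spec.name))
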