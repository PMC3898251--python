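"""Vector geometry for side-chain modelling.

Distances, bond angles, signed torsion angles, ideal tetrahedral C-beta
reconstruction from backbone atoms, and forward kinematics placing the
cysteine S-gamma as a function of the chi1 torsion.

All angles are in degrees, all distances in Angstroms. The torsion sign
convention is the standard one used for protein dihedrals: looking down
the p2->p3 bond, the torsion is positive when the far bond (p3->p4) is
rotated clockwise relative to the near bond (p1->p2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "IdealParams",
    "SidechainPose",
    "distance",
    "bond_angle",
    "dihedral",
    "place_atom",
    "construct_cbeta",
    "place_sgamma",
]

_EPS = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when points are coincident or collinear where they must not be."""


@dataclass(frozen=True)
class IdealParams:
    """Ideal covalent geometry of the cystine side chain.

    These follow standard cystine stereochemistry and are configuration,
    not hard-wired constants.

    Attributes
    ----------
    d_ca_cb : CA-CB bond length (A).
    d_cb_sg : CB-SG bond length (A).
    d_ss : SG-SG disulfide bond length (A).
    ang_ca_cb_sg : CA-CB-SG bond angle (deg).
    ang_cb_s_s : CB-SG-SG' bond angle (deg).
    ang_n_ca_cb : N-CA-CB (and C-CA-CB) tetrahedral angle used when
        rebuilding C-beta from backbone coordinates (deg).
    """

    d_ca_cb: float = 1.53
    d_cb_sg: float = 1.81
    d_ss: float = 2.04
    ang_ca_cb_sg: float = 114.6
    ang_cb_s_s: float = 104.9
    ang_n_ca_cb: float = 110.5

    def __post_init__(self) -> None:
        for name in ("d_ca_cb", "d_cb_sg", "d_ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ang_ca_cb_sg", "ang_cb_s_s", "ang_n_ca_cb"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees")


@dataclass(frozen=True)
class SidechainPose:
    """An idealized CB/SG placement for one residue at a given chi1."""

    residue_key: Tuple[str, int, str]
    chi1: float
    cb: np.ndarray
    sg: np.ndarray


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def distance(p1, p2) -> float:
    return float(np.linalg.norm(_as_vec(p2) - _as_vec(p1)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    a = _as_vec(p1) - _as_vec(p2)
    b = _as_vec(p3) - _as_vec(p2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        raise DegenerateGeometryError("coincident points in bond angle")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Uses the atan2 formulation; invariant under rigid-body transforms and
    under reversal of the point order, antisymmetric under mirror
    reflection.
    """
    p1, p2, p3, p4 = map(_as_vec, (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(b1) < _EPS or nb2 < _EPS or np.linalg.norm(b3) < _EPS:
        raise DegenerateGeometryError("coincident consecutive points in dihedral")
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    if np.linalg.norm(c12) < _EPS or np.linalg.norm(c23) < _EPS:
        raise DegenerateGeometryError("collinear points in dihedral")
    y = np.dot(np.cross(c12, c23), b2) / nb2
    x = np.dot(c12, c23)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond_length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates on the chain a-b-c-D.

    D satisfies |D - c| = bond_length, angle(b, c, D) = angle_deg and
    dihedral(a, b, c, D) = torsion_deg.
    """
    a, b, c = map(_as_vec, (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < _EPS or np.linalg.norm(ab) < _EPS:
        raise DegenerateGeometryError("coincident points in place_atom")
    bc /= nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear reference points in place_atom")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def construct_cbeta(n, ca, c, params: IdealParams = IdealParams()) -> np.ndarray:
    """Rebuild the ideal tetrahedral C-beta from the N, CA, C backbone atoms.

    The C-beta sits at distance ``d_ca_cb`` from CA with N-CA-CB and
    C-CA-CB angles both ``ang_n_ca_cb``, on the side consistent with
    L-amino-acid chirality (improper torsion N-CA-C-CB positive, about
    +122.5 degrees for ideal backbone geometry).
    """
    n, ca, c = map(_as_vec, (n, ca, c))
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError("coincident backbone atoms")
    u /= nu
    v /= nv
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nw < _EPS:
        raise DegenerateGeometryError("collinear backbone atoms N, CA, C")
    w /= nw
    cos_t = np.cos(np.radians(params.ang_n_ca_cb))
    dot_uv = float(np.dot(u, v))
    # direction d with d.u = d.v = cos_t: d = alpha(u+v) + beta w
    alpha = cos_t / (1.0 + dot_uv)
    rem = 1.0 - alpha * alpha * (2.0 + 2.0 * dot_uv)
    if rem < 0.0:
        raise DegenerateGeometryError("backbone angle incompatible with tetrahedral C-beta")
    # -w (v x u side) puts CB on the L-configuration side: torsion N-CA-C-CB > 0
    beta = -np.sqrt(rem)
    d = alpha * (u + v) + beta * w
    return ca + params.d_ca_cb * d


def place_sgamma(n, ca, cb, chi1: float, params: IdealParams = IdealParams()) -> np.ndarray:
    """Place SG from N, CA, CB at torsion chi1 = dihedral(N, CA, CB, SG)."""
    return place_atom(n, ca, cb, params.d_cb_sg, params.ang_ca_cb_sg, chi1)
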