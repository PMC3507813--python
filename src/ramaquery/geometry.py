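"""Torsion-angle computation and per-residue dihedral assignment.

Angles are reported in degrees on the half-open interval (-180, 180],
with the -180/+180 seam resolved to +180 so the trans conformation has a
single representation.  An angle that cannot be computed (chain terminus,
chain break, missing atom, degenerate geometry) is ``None``, never an
exception: undefined angles are ordinary values downstream, so partially
defined elements can still be filtered on their defined positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_io import ChainModel

__all__ = [
    "ResidueConformation",
    "torsion",
    "residue_dihedrals",
    "is_consecutive",
    "circular_difference",
    "normalize_angle",
    "CHI1_GAMMA_ATOM",
    "CHAIN_BREAK_CN_MAX",
]

# Fourth atom of the chi1 torsion N-CA-CB-X, by residue type (standard
# heavy-atom convention).  GLY has no CB and ALA no gamma atom, so chi1 is
# undefined for both.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}

# Maximum C(i)-N(i+1) distance (Angstrom) for two residues to be considered
# covalently continuous.  Generous against the ~1.33 A peptide bond but far
# below typical gap distances.
CHAIN_BREAK_CN_MAX = 2.5

_DEGENERACY_EPS = 1e-10


@dataclass(frozen=True)
class ResidueConformation:
    """The (phi, psi, chi1) dihedral triple of one residue, each optional."""

    phi: Optional[float] = None
    psi: Optional[float] = None
    chi1: Optional[float] = None

    def angle(self, name: str) -> Optional[float]:
        return getattr(self, name)


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto (-180, 180], sending -180 to +180."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def circular_difference(a: float, b: float) -> float:
    """Absolute circular distance between two angles in degrees, in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def torsion(p1, p2, p3, p4) -> Optional[float]:
    """Torsion angle of four points in degrees, IUPAC sign convention.

    Looking along p2->p3, the angle is positive when p3->p4 is rotated
    clockwise from p2->p1.  Returns ``None`` for degenerate geometry
    (coincident consecutive points or collinear triples).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if (
        norm_b2 < _DEGENERACY_EPS
        or np.linalg.norm(n1) < _DEGENERACY_EPS
        or np.linalg.norm(n2) < _DEGENERACY_EPS
    ):
        return None
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def is_consecutive(chain: ChainModel, i: int) -> bool:
    """Whether residues i and i+1 of *chain* are covalently continuous.

    Continuity requires author numbering advancing by one (or an
    insertion-code step at the same number) and a C(i)-N(i+1) distance of
    at most ``CHAIN_BREAK_CN_MAX``.
    """
    if i < 0 or i + 1 >= len(chain.residues):
        return False
    cur, nxt = chain.residues[i], chain.residues[i + 1]
    delta = nxt.auth_seq - cur.auth_seq
    numbering_ok = delta == 1 or (delta == 0 and nxt.icode != cur.icode)
    if not numbering_ok:
        return False
    c = cur.atoms.get("C")
    n = nxt.atoms.get("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(np.asarray(c.coords) - np.asarray(n.coords))) <= CHAIN_BREAK_CN_MAX


def _coords(chain: ChainModel, i: int, name: str):
    atom = chain.residues[i].atoms.get(name)
    return None if atom is None else atom.coords


def residue_dihedrals(chain: ChainModel, i: int) -> ResidueConformation:
    """Compute (phi, psi, chi1) for residue *i* of *chain*.

    phi is undefined at the chain start or across a break, psi at the chain
    end or across a break, chi1 for gly/ala or when the side-chain atoms
    are missing.
    """
    if not 0 <= i < len(chain.residues):
        raise IndexError(f"residue index {i} out of range for chain of length {len(chain.residues)}")

    res = chain.residues[i]
    n_i = _coords(chain, i, "N")
    ca_i = _coords(chain, i, "CA")
    c_i = _coords(chain, i, "C")

    phi = psi = chi1 = None
    if i > 0 and is_consecutive(chain, i - 1):
        c_prev = _coords(chain, i - 1, "C")
        if all(p is not None for p in (c_prev, n_i, ca_i, c_i)):
            phi = torsion(c_prev, n_i, ca_i, c_i)
    if i + 1 < len(chain.residues) and is_consecutive(chain, i):
        n_next = _coords(chain, i + 1, "N")
        if all(p is not None for p in (n_i, ca_i, c_i, n_next)):
            psi = torsion(n_i, ca_i, c_i, n_next)

    gamma_name = CHI1_GAMMA_ATOM.get(res.res_name)
    if gamma_name is not None:
        cb = _coords(chain, i, "CB")
        gamma = _coords(chain, i, gamma_name)
        if all(p is not None for p in (n_i, ca_i, cb, gamma)):
            chi1 = torsion(n_i, ca_i, cb, gamma)

    return ResidueConformation(phi=phi, psi=psi, chi1=chi1)
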