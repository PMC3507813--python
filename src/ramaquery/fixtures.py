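"""Synthetic backbones with prescribed dihedrals, for tests and demos.

Chains are built by sequential internal-to-Cartesian (NeRF-style)
construction with fixed ideal bond lengths and angles, so that
re-measuring a built chain recovers the prescribed phi/psi (and
optionally chi1) exactly, to numerical precision.  This substitutes for
real structures wherever a chain with known dihedrals is needed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .geometry import CHI1_GAMMA_ATOM
from .structure_io import AtomRecord, ChainModel, ONE_TO_THREE, ResidueRecord

__all__ = ["BackboneSpec", "build_backbone", "write_pdb", "IDEAL"]

# Ideal backbone geometry (Angstrom / degrees).  The bond values follow
# standard small-molecule-refined averages; dihedrals, not coordinates,
# are the quantities of interest, so these are fixed constants.
IDEAL = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "CA_CB": 1.530,
    "CB_G": 1.520,
    "ang_N_CA_C": 111.0,
    "ang_CA_C_N": 117.2,
    "ang_C_N_CA": 121.7,
    "ang_N_CA_CB": 110.5,
    "ang_CA_CB_G": 114.0,
    # improper torsion N-C-CA-CB fixing the L-configuration of the CB branch
    "improper_N_C_CA_CB": -122.6,
}


@dataclass
class BackboneSpec:
    """Prescription for a synthetic chain: per-residue (phi, psi) and sequence.

    phi of the first residue and psi of the last are unused (those angles
    are undefined at chain termini) but must still be supplied.  ``omega``
    may be a single value applied to every peptide bond or one value per
    bond (length n-1); ``chi1`` optionally prescribes the first side-chain
    torsion per residue, realised by placing the residue's gamma atom.
    """

    angles: Sequence[tuple[float, float]]
    sequence: str = ""
    omega: float | Sequence[float] = 180.0
    chi1: Optional[Sequence[Optional[float]]] = None

    def __post_init__(self):
        if not self.sequence:
            self.sequence = "A" * len(self.angles)
        if len(self.sequence) != len(self.angles):
            raise ValueError("sequence and angles must have the same length")
        if len(self.angles) < 2:
            raise ValueError("a backbone needs at least 2 residues")
        if self.chi1 is not None and len(self.chi1) != len(self.angles):
            raise ValueError("chi1 list must match the number of residues")
        for aa in self.sequence:
            if aa.upper() not in ONE_TO_THREE:
                raise ValueError(f"unknown 1-letter residue code {aa!r}")

    def omega_at(self, bond_index: int) -> float:
        if isinstance(self.omega, (int, float)):
            return float(self.omega)
        omegas = list(self.omega)
        if len(omegas) != len(self.angles) - 1:
            raise ValueError("omega list must have one value per peptide bond (n-1)")
        return float(omegas[bond_index])


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place point d with |c-d| = bond, angle(b,c,d) = angle, torsion(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(spec: BackboneSpec) -> ChainModel:
    """Construct a :class:`ChainModel` realising *spec*'s dihedrals exactly.

    N/CA/C are placed by NeRF chain extension; CB is added tetrahedrally
    for every non-gly residue, and a gamma atom at the prescribed chi1
    where ``spec.chi1`` gives one.
    """
    n_res = len(spec.angles)
    seq3 = [ONE_TO_THREE[aa.upper()] for aa in spec.sequence]

    coords: list[dict[str, np.ndarray]] = []
    # Canonical first residue: N at origin, CA on +x, C in the xy-plane.
    n0 = np.zeros(3)
    ca0 = np.array([IDEAL["N_CA"], 0.0, 0.0])
    ang = math.radians(180.0 - IDEAL["ang_N_CA_C"])
    c0 = ca0 + IDEAL["CA_C"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = coords[i - 1]
        psi_prev = spec.angles[i - 1][1]
        phi_i = spec.angles[i][0]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         IDEAL["C_N"], IDEAL["ang_CA_C_N"], psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          IDEAL["N_CA"], IDEAL["ang_C_N_CA"], spec.omega_at(i - 1))
        c_i = place_atom(prev["C"], n_i, ca_i,
                         IDEAL["CA_C"], IDEAL["ang_N_CA_C"], phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, res3 in enumerate(seq3):
        if res3 == "GLY":
            continue
        atoms = coords[i]
        atoms["CB"] = place_atom(atoms["N"], atoms["C"], atoms["CA"],
                                 IDEAL["CA_CB"], IDEAL["ang_N_CA_CB"],
                                 IDEAL["improper_N_C_CA_CB"])
        chi1 = spec.chi1[i] if spec.chi1 is not None else None
        gamma_name = CHI1_GAMMA_ATOM.get(res3)
        if chi1 is not None and gamma_name is not None:
            atoms[gamma_name] = place_atom(atoms["N"], atoms["CA"], atoms["CB"],
                                           IDEAL["CB_G"], IDEAL["ang_CA_CB_G"], chi1)

    residues = [
        ResidueRecord(
            chain_id="A",
            auth_seq=i + 1,
            icode="",
            res_name=seq3[i],
            atoms={name: AtomRecord(name=name, coords=xyz) for name, xyz in coords[i].items()},
        )
        for i in range(n_res)
    ]
    return ChainModel(source_id="FIXT", chain_id="A", residues=residues)


_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def write_pdb(chain: ChainModel, path: os.PathLike | str) -> None:
    """Write *chain* as a standard PDB file (coordinates to 3 decimals)."""
    if not chain.residues:
        raise ValueError("cannot write an empty chain")
    structure = gemmi.Structure()
    structure.name = chain.source_id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.auth_seq, res.icode or " ")
        gres.het_flag = "A"
        for atom in res.atoms.values():
            gatom = gemmi.Atom()
            gatom.name = atom.name
            gatom.pos = gemmi.Position(*atom.coords)
            gatom.occ = atom.occupancy
            gatom.element = gemmi.Element(_ELEMENT.get(atom.name[:1], "C"))
            gres.add_atom(gatom)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(os.fspath(path))
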