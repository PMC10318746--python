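"""Ideal-geometry amino-acid templates: side-chain internal coordinates,
covalent bond lists and chi-torsion definitions for the 20 standard residues.

Heavy atoms only (the pipeline operates on hydrogen-free crystal-style
models). Side chains are described in NeRF internal coordinates: each atom is
placed from three previously placed atoms (A, B, C) with a bond length C-D,
angle B-C-D and torsion A-B-C-D. Torsions are either tied to a chi angle
(("chi", k, offset_deg)) or fixed (("fixed", deg)) for rigid groups such as
aromatic rings and the guanidinium/carboxylate planes.

The geometry is idealised (ring-closure bonds for PRO/HIS/PHE/TYR/TRP are
implied by the bond list, not re-solved), which is adequate for the reduced
scoring model used here.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .structure_io import Atom

__all__ = [
    "SIDECHAIN_TEMPLATES",
    "RESIDUE_BONDS",
    "N_CHI",
    "AMINO_ACIDS",
    "build_side_chain",
    "build_residue",
    "sidechain_atom_names",
]

# (name, element, (A, B, C), bond, angle_deg, torsion_spec)
_T = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.42, 110.5, ("chi", 1, 0.0))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.81, 114.0, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.43, 109.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0.0)),
    ],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.50, 105.0, ("chi", 2, 0.0)),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, ("fixed", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fixed", 0.0)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 113.0, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.7, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0.0)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("NE", "N", ("CB", "CG", "CD"), 1.46, 111.8, ("chi", 3, 0.0)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.8, ("chi", 4, 0.0)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, ("fixed", 0.0)),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, ("fixed", 180.0)),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.36, 131.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, ("fixed", 180.0)),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.0, ("fixed", 180.0)),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.7, ("chi", 2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.0, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.0, ("fixed", 180.0)),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, ("fixed", 0.0)),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, ("fixed", 180.0)),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.6, ("fixed", 180.0)),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.5, ("fixed", 0.0)),
    ],
    "TYR": [],  # filled below from PHE + OH
}
_T["TYR"] = list(_T["PHE"]) + [("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, ("fixed", 180.0))]

SIDECHAIN_TEMPLATES = _T
AMINO_ACIDS = sorted(SIDECHAIN_TEMPLATES)

#: number of rotatable chi angles per residue type
N_CHI = {
    name: max([spec[1] for *_, spec in atoms if spec[0] == "chi"], default=0)
    for name, atoms in SIDECHAIN_TEMPLATES.items()
}

# ring-closure and backbone bonds not implied by the NeRF parent relation
_EXTRA_BONDS = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
}

#: dihedral(N, C, CA, CB) realising L-configuration at CA (sign fixed by a
#: CIP check in the test suite)
_CB_TORSION_DEG = 122.5


def _residue_bonds(resname: str) -> list[tuple[str, str]]:
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    atoms = SIDECHAIN_TEMPLATES.get(resname, [])
    if resname != "GLY":
        bonds.append(("CA", "CB"))
    for name, _el, parents, *_ in atoms:
        bonds.append((parents[2], name))
    bonds.extend(_EXTRA_BONDS.get(resname, []))
    return bonds


RESIDUE_BONDS: dict[str, list[tuple[str, str]]] = {r: _residue_bonds(r) for r in AMINO_ACIDS}


def sidechain_atom_names(resname: str) -> list[str]:
    names = [] if resname == "GLY" else ["CB"]
    names += [rec[0] for rec in SIDECHAIN_TEMPLATES[resname]]
    return names


def build_side_chain(
    resname: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chis: tuple[float, ...] = (),
) -> list[tuple[str, str, np.ndarray]]:
    """Place side-chain heavy atoms onto an existing backbone.

    ``chis`` are chi angles in degrees, length >= N_CHI[resname] (extras
    ignored). Returns (atom_name, element, position) tuples including CB.
    """
    if resname not in SIDECHAIN_TEMPLATES:
        raise KeyError(f"unknown residue type {resname!r}")
    need = N_CHI[resname]
    if len(chis) < need:
        raise ValueError(f"{resname} needs {need} chi angles, got {len(chis)}")
    pos: dict[str, np.ndarray] = {"N": np.asarray(n, float), "CA": np.asarray(ca, float), "C": np.asarray(c, float)}
    out: list[tuple[str, str, np.ndarray]] = []
    if resname != "GLY":
        cb = place_atom(
            pos["N"], pos["C"], pos["CA"], 1.53, np.deg2rad(110.4), np.deg2rad(_CB_TORSION_DEG)
        )
        pos["CB"] = cb
        out.append(("CB", "C", cb))
    for name, element, (a, b, cc_), length, angle, tors in SIDECHAIN_TEMPLATES[resname]:
        if tors[0] == "chi":
            _, k, offset = tors
            torsion = np.deg2rad(chis[k - 1] + offset)
        else:
            torsion = np.deg2rad(tors[1])
        p = place_atom(pos[a], pos[b], pos[cc_], length, np.deg2rad(angle), torsion)
        pos[name] = p
        out.append((name, element, p))
    return out


def build_residue(
    resname: str,
    *,
    chis: tuple[float, ...] = (),
    chain_id: str = "A",
    residue_seq: int = 1,
    serial_start: int = 1,
) -> list[Atom]:
    """Construct a free-standing residue (backbone + side chain) at the origin.

    Backbone: N at origin, CA along +x, C in the xy-plane, carbonyl O placed
    with a fixed torsion. Intended for synthetic fixtures; rigid-place the
    returned atoms wherever needed.
    """
    n = np.zeros(3)
    ca = np.array([1.46, 0.0, 0.0])
    theta = np.deg2rad(111.0)
    c = ca + 1.52 * np.array([-np.cos(theta), np.sin(theta), 0.0])
    o = place_atom(n, ca, c, 1.23, np.deg2rad(120.5), np.deg2rad(-45.0))
    records = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
    need = N_CHI[resname]
    if len(chis) < need:
        chis = tuple(chis) + (180.0,) * (need - len(chis))
    records += build_side_chain(resname, n, ca, c, chis)
    atoms = []
    for i, (name, element, p) in enumerate(records):
        atoms.append(
            Atom(
                serial=serial_start + i,
                name=name,
                element=element,
                position=np.asarray(p, float),
                residue_name=resname,
                chain_id=chain_id,
                residue_seq=residue_seq,
                record_kind="ATOM",
            )
        )
    return atoms
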