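"""Pocket residue selection and polar-contact (hydrogen-bond proxy) detection.

With hydrogen-free crystal-style models, a hydrogen bond is approximated by
its heavy-atom geometry: a donor and an acceptor (N/O, plus S on cysteine as
a donor) separated by 2.4-3.5 A, with every covalent antecedent of both atoms
making an angle of at least 90 degrees with the contact vector — the common
visualization-tool definition of a "polar contact". The thresholds are
exposed in :class:`ContactCriteria` because published per-residue bond counts
are sensitive to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import bond_angle
from .ligand_model import COVALENT_RADII, LigandMolecule
from .structure_io import Atom, StructureModel

__all__ = [
    "ContactCriteria",
    "PolarContact",
    "residues_within",
    "polar_contacts",
    "residue_residue_contacts",
    "contact_report",
    "DONORS",
    "ACCEPTORS",
]

# ---------------------------------------------------------------------------
# donor / acceptor typing (side-chain heavy atoms)
# ---------------------------------------------------------------------------

DONORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"},
}

ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}


@dataclass
class ContactCriteria:
    """Geometric thresholds for pocket selection and polar-contact detection."""

    neighbor_cutoff: float = 4.0  # A, pocket residue selection
    polar_distance_max: float = 3.5  # A, donor-acceptor heavy-atom separation
    polar_distance_min: float = 2.4  # A
    angle_min: float = 90.0  # deg, antecedent-atom-partner angle
    include_backbone: bool = True  # backbone N (donor) / O (acceptor)

    def __post_init__(self):
        if not (0.0 < self.polar_distance_min < self.polar_distance_max):
            raise ValueError("need 0 < polar_distance_min < polar_distance_max")
        if not np.isfinite(self.neighbor_cutoff):
            raise ValueError("neighbor_cutoff must be finite")


@dataclass
class PolarContact:
    """One donor-acceptor interaction."""

    residue: tuple[str, int, str]  # (chain, seq, name) of the protein residue
    atom_a: Atom  # protein atom
    atom_b: Atom  # ligand atom, or second-residue atom for residue-residue
    distance: float
    kind: str = "protein-ligand"  # "protein-ligand" | "residue-residue"
    partner_residue: tuple[str, int, str] | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _protein_atoms(model: StructureModel) -> list[Atom]:
    return [a for a in model.atoms if not a.is_hetero and a.element != "H"]


def _residue_key(a: Atom) -> tuple[str, int, str]:
    return (a.chain_id, a.residue_seq, a.residue_name)


def _protein_polar_roles(a: Atom, criteria: ContactCriteria) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a protein heavy atom."""
    res, name = a.residue_name, a.name
    donor = name in DONORS.get(res, set())
    acceptor = name in ACCEPTORS.get(res, set())
    if criteria.include_backbone:
        if name == "N" and res != "PRO":
            donor = True
        if name == "O":
            acceptor = True
    return donor, acceptor


def _ligand_polar_roles(a: Atom) -> tuple[bool, bool]:
    """Alditol hydroxyl oxygens are both donor and acceptor; N generic."""
    if a.element == "O":
        return True, True
    if a.element == "N":
        return True, True
    return False, False


def _antecedents(atom: Atom, residue_atoms: list[Atom]) -> list[Atom]:
    """Covalently bonded heavy neighbours within the same residue (by distance)."""
    out = []
    r0 = COVALENT_RADII.get(atom.element, 0.77)
    for other in residue_atoms:
        if other is atom or other.element == "H":
            continue
        r1 = COVALENT_RADII.get(other.element, 0.77)
        if np.linalg.norm(atom.position - other.position) < r0 + r1 + 0.45:
            out.append(other)
    return out


def _ligand_antecedents(atom_idx: int, ligand: LigandMolecule) -> list[Atom]:
    return [
        ligand.atoms[j]
        for j in ligand.neighbors(atom_idx)
        if ligand.atoms[j].element != "H"
    ]


def _angles_ok(
    atom: Atom, partner: Atom, antecedents: list[Atom], angle_min_deg: float
) -> bool:
    """Every antecedent-atom-partner angle must open at least angle_min."""
    for x in antecedents:
        ang = np.rad2deg(bond_angle(x.position, atom.position, partner.position))
        if ang < angle_min_deg:
            return False
    return True


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def residues_within(
    model: StructureModel, ligand: LigandMolecule, cutoff: float
) -> list[tuple[str, int, str]]:
    """Protein residues with any heavy atom within ``cutoff`` of any ligand
    heavy atom, sorted by (chain, residue number)."""
    lig_xyz = np.array([a.position for a in ligand.atoms if a.element != "H"])
    if lig_xyz.size == 0:
        raise ValueError("ligand has no heavy atoms")
    prot = _protein_atoms(model)
    if not prot or cutoff <= 0:
        return []
    tree = cKDTree(np.array([a.position for a in prot]))
    hit: set[tuple[str, int, str]] = set()
    for idx_list in tree.query_ball_point(lig_xyz, r=cutoff):
        for i in idx_list:
            hit.add(_residue_key(prot[i]))
    return sorted(hit, key=lambda k: (k[0], k[1]))


def polar_contacts(
    model: StructureModel,
    ligand: LigandMolecule,
    criteria: ContactCriteria | None = None,
) -> list[PolarContact]:
    """Protein-ligand polar contacts under the geometric criteria.

    Each undirected protein-atom/ligand-atom pair is reported at most once;
    it qualifies if either role assignment (protein donor -> ligand acceptor
    or vice versa) satisfies the distance and antecedent-angle windows.
    """
    criteria = criteria or ContactCriteria()
    lig_heavy = [(i, a) for i, a in enumerate(ligand.atoms) if a.element != "H"]
    if not lig_heavy:
        raise ValueError("ligand has no heavy atoms")
    residues = model.residues()
    out: list[PolarContact] = []
    prot = _protein_atoms(model)
    if not prot:
        return out
    tree = cKDTree(np.array([a.position for a in prot]))
    for li, la in lig_heavy:
        ld, lacc = _ligand_polar_roles(la)
        if not (ld or lacc):
            continue
        for pi in tree.query_ball_point(la.position, r=criteria.polar_distance_max):
            pa = prot[pi]
            pdon, pacc = _protein_polar_roles(pa, criteria)
            if not ((pdon and lacc) or (pacc and ld)):
                continue
            d = float(np.linalg.norm(pa.position - la.position))
            if not (criteria.polar_distance_min <= d <= criteria.polar_distance_max):
                continue
            res_atoms = residues[_residue_key(pa)]
            if not _angles_ok(pa, la, _antecedents(pa, res_atoms), criteria.angle_min):
                continue
            if not _angles_ok(la, pa, _ligand_antecedents(li, ligand), criteria.angle_min):
                continue
            out.append(
                PolarContact(
                    residue=_residue_key(pa),
                    atom_a=pa,
                    atom_b=la,
                    distance=d,
                    kind="protein-ligand",
                )
            )
    return out


def residue_residue_contacts(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    restrict_to: Iterable[tuple[str, int, str]] | None = None,
) -> list[PolarContact]:
    """Polar contacts between side-chain/backbone polar atoms of *different*
    residues (optionally restricted to a residue subset, e.g. the pocket)."""
    criteria = criteria or ContactCriteria()
    residues = model.residues()
    wanted = set(restrict_to) if restrict_to is not None else None
    polar: list[tuple[Atom, bool, bool]] = []
    for a in _protein_atoms(model):
        if wanted is not None and _residue_key(a) not in wanted:
            continue
        d, acc = _protein_polar_roles(a, criteria)
        if d or acc:
            polar.append((a, d, acc))
    out: list[PolarContact] = []
    for i in range(len(polar)):
        ai, di, acci = polar[i]
        for j in range(i + 1, len(polar)):
            aj, dj, accj = polar[j]
            ki, kj = _residue_key(ai), _residue_key(aj)
            if ki == kj:
                continue
            if abs(ai.residue_seq - aj.residue_seq) == 1 and ai.chain_id == aj.chain_id:
                # skip backbone-backbone pairs of adjacent residues
                if ai.name in ("N", "O") and aj.name in ("N", "O"):
                    continue
            if not ((di and accj) or (dj and acci)):
                continue
            d = float(np.linalg.norm(ai.position - aj.position))
            if not (criteria.polar_distance_min <= d <= criteria.polar_distance_max):
                continue
            if not _angles_ok(ai, aj, _antecedents(ai, residues[ki]), criteria.angle_min):
                continue
            if not _angles_ok(aj, ai, _antecedents(aj, residues[kj]), criteria.angle_min):
                continue
            out.append(
                PolarContact(
                    residue=ki,
                    atom_a=ai,
                    atom_b=aj,
                    distance=d,
                    kind="residue-residue",
                    partner_residue=kj,
                )
            )
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

CountsLike = Iterable[PolarContact] | Mapping


def _to_counts(state) -> dict:
    """Normalise a contact list or residue->count mapping to a count dict."""
    if isinstance(state, Mapping):
        return dict(state)
    counts: dict = {}
    for c in state:
        counts[c.residue] = counts.get(c.residue, 0) + 1
    return counts


def _row_label(key) -> str:
    if isinstance(key, tuple):
        if len(key) == 3:
            return f"{key[1]} {key[2]}"
        if len(key) == 2:
            return f"{key[0]} {key[1]}"
    return str(key)


def _sort_key(key):
    if isinstance(key, tuple) and len(key) >= 2 and isinstance(key[-2], int):
        return (0, key[-2])
    return (1, str(key))


def contact_report(
    states: Mapping[str, CountsLike],
    pocket_residues: Iterable | None = None,
) -> pd.DataFrame:
    """Per-residue polar-bond counts across pipeline states, with totals.

    ``states`` maps a column label (e.g. "before mutation", "after mutation",
    "after relax") to either a list of :class:`PolarContact` or a residue ->
    count mapping. Residues listed in ``pocket_residues`` but absent from
    every state appear with zero counts (pocket residues with only *potential*
    for polar bonds). The final row, labelled TOTAL, sums each column.
    """
    counts = {label: _to_counts(state) for label, state in states.items()}
    keys = set()
    for c in counts.values():
        keys.update(c.keys())
    if pocket_residues is not None:
        keys.update(pocket_residues)
    ordered = sorted(keys, key=_sort_key)
    data = {
        label: [counts[label].get(k, 0) for k in ordered] for label in counts
    }
    df = pd.DataFrame(data, index=[_row_label(k) for k in ordered], dtype=int)
    df.loc["TOTAL"] = df.sum(axis=0)
    return df
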