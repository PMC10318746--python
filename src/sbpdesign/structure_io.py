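"""Read, manipulate and write PDB-format structures.

The in-memory model is a flat, ordered list of :class:`Atom` records grouped on
demand into chains and residues. Parsing and serialisation of the fixed-column
PDB format are delegated to :mod:`biotite`; this module owns the domain model
(monomer extraction, ligand extraction/removal, orphan-heteroatom chain
assignment) used by the rest of the pipeline.

Conventions
-----------
* Alternate locations: only blank or 'A' conformers are kept.
* Waters (HOH) are dropped by default.
* Only the first MODEL of a multi-model file is read.
* Residue numbering follows the author numbering in the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "StructureModel",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "extract_monomer",
    "extract_ligand",
    "remove_ligand",
]

#: residue names treated as solvent
WATER_NAMES = {"HOH", "WAT", "DOD"}


class EmptyStructureError(ValueError):
    """Raised when a file or model contains no coordinate records."""


@dataclass
class Atom:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    position: np.ndarray  # (3,) float, Angstrom
    alt_loc: str = ""
    residue_name: str = "UNK"
    chain_id: str = "A"
    residue_seq: int = 1
    occupancy: float = 1.0
    b_factor: float = 0.0
    record_kind: str = "ATOM"  # "ATOM" | "HETATM"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hetero(self) -> bool:
        return self.record_kind == "HETATM"

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class StructureModel:
    """An ordered collection of atoms with derived chain/residue groupings."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def copy(self) -> "StructureModel":
        return StructureModel([a.copy() for a in self.atoms])

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    @property
    def chain_ids(self) -> list[str]:
        """Chain ids of protein (ATOM) records, in order of first appearance."""
        seen: list[str] = []
        for a in self.atoms:
            if not a.is_hetero and a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Group atoms by (chain_id, residue_seq, residue_name), order preserved."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(a)
        return out

    def het_residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        return {k: v for k, v in self.residues().items() if all(a.is_hetero for a in v)}

    def renumber_serials(self) -> None:
        for i, a in enumerate(self.atoms, start=1):
            a.serial = i

    def extend(self, atoms: Iterable[Atom]) -> None:
        self.atoms.extend(atoms)


# ---------------------------------------------------------------------------
# file I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr: bst.AtomArray) -> StructureModel:
    atoms = []
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    occ = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length())
    )
    bf = (
        arr.get_annotation("b_factor")
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length())
    )
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).capitalize(),
                position=np.array(arr.coord[i], dtype=float),
                alt_loc="",
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                residue_seq=int(arr.res_id[i]),
                occupancy=float(occ[i]),
                b_factor=float(bf[i]),
                record_kind="HETATM" if bool(arr.hetero[i]) else "ATOM",
            )
        )
    return StructureModel(atoms)


def _to_atom_array(model: StructureModel) -> bst.AtomArray:
    n = len(model.atoms)
    arr = bst.AtomArray(n)
    arr.coord = model.coords
    arr.set_annotation("chain_id", np.array([a.chain_id for a in model.atoms], dtype="U4"))
    arr.set_annotation("res_id", np.array([a.residue_seq for a in model.atoms], dtype=int))
    arr.set_annotation("res_name", np.array([a.residue_name for a in model.atoms], dtype="U5"))
    arr.set_annotation("atom_name", np.array([a.name for a in model.atoms], dtype="U6"))
    arr.set_annotation("element", np.array([a.element.upper() for a in model.atoms], dtype="U2"))
    arr.set_annotation("hetero", np.array([a.is_hetero for a in model.atoms], dtype=bool))
    arr.set_annotation("atom_id", np.array([a.serial for a in model.atoms], dtype=int))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms], dtype=float))
    arr.set_annotation("b_factor", np.array([a.b_factor for a in model.atoms], dtype=float))
    return arr


def read_pdb(path: str | Path, *, keep_waters: bool = False) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only MODEL 1 is read; alternate locations other than blank/'A' are dropped;
    waters are dropped unless ``keep_waters``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(
            model=1, altloc="first", extra_fields=["atom_id", "occupancy", "b_factor"]
        )
    except Exception as exc:  # no coordinate records at all
        raise EmptyStructureError(f"no ATOM/HETATM records in {path}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no ATOM/HETATM records in {path}")
    model = _from_atom_array(arr)
    if not keep_waters:
        model = StructureModel([a for a in model.atoms if a.residue_name not in WATER_NAMES])
    if len(model.atoms) == 0:
        raise EmptyStructureError(f"no non-solvent atoms in {path}")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialise to fixed-column PDB; inverse of :func:`read_pdb` on the data model."""
    if len(model.atoms) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# extraction operations
# ---------------------------------------------------------------------------

def _nearest_protein_chain(het_atoms: list[Atom], model: StructureModel) -> str:
    """Assign an orphan het group to the protein chain with the closest heavy atom."""
    het_xyz = np.array([a.position for a in het_atoms])
    best_chain, best_d = None, np.inf
    for cid in model.chain_ids:
        xyz = np.array([a.position for a in model.atoms if a.chain_id == cid and not a.is_hetero])
        if len(xyz) == 0:
            continue
        d = np.min(np.linalg.norm(xyz[:, None, :] - het_xyz[None, :, :], axis=-1))
        if d < best_d:
            best_chain, best_d = cid, d
    if best_chain is None:
        raise LookupError("model contains no protein chains to assign heteroatoms to")
    return best_chain


def extract_monomer(model: StructureModel, keep_chain: str) -> StructureModel:
    """Keep one protein chain plus the heteroatom groups that belong to it.

    Het groups sharing the chain id are kept directly; het groups with a chain
    id that matches no protein chain are assigned to the nearest protein chain
    by minimum heavy-atom distance.
    """
    protein_chains = set(model.chain_ids)
    if keep_chain not in protein_chains:
        raise LookupError(f"chain {keep_chain!r} not present (have {sorted(protein_chains)})")
    kept: list[Atom] = []
    for key, res_atoms in model.residues().items():
        chain_id = key[0]
        if all(a.is_hetero for a in res_atoms):
            owner = chain_id if chain_id in protein_chains else _nearest_protein_chain(res_atoms, model)
            if owner == keep_chain:
                kept.extend(a.copy() for a in res_atoms)
        elif chain_id == keep_chain:
            kept.extend(a.copy() for a in res_atoms)
    out = StructureModel(kept)
    out.renumber_serials()
    return out


def _het_residue_atoms(
    model: StructureModel, het_code: str, chain: str | None
) -> list[Atom]:
    groups = [
        atoms
        for (cid, _seq, name), atoms in model.het_residues().items()
        if name == het_code and (chain is None or cid == chain)
    ]
    if not groups:
        raise LookupError(f"no HETATM residue {het_code!r} in model")
    if len(groups) > 1:
        raise LookupError(
            f"{len(groups)} copies of {het_code!r} present; disambiguate with chain="
        )
    return groups[0]


def extract_ligand(model: StructureModel, het_code: str, *, chain: str | None = None):
    """Return the named het group as a :class:`~sbpdesign.ligand_model.LigandMolecule`.

    The source model is left unchanged; use :func:`remove_ligand` for the
    complementary ligand-free structure.
    """
    from .ligand_model import ligand_from_atoms  # local import, avoids cycle

    atoms = [a.copy() for a in _het_residue_atoms(model, het_code, chain)]
    return ligand_from_atoms(atoms)


def remove_ligand(model: StructureModel, het_code: str, *, chain: str | None = None) -> StructureModel:
    """Return a copy of the model without the named het group."""
    target = _het_residue_atoms(model, het_code, chain)
    target_ids = {id(a) for a in target}
    out = StructureModel([a.copy() for a in model.atoms if id(a) not in target_ids])
    if len(out.atoms) == 0:
        raise EmptyStructureError("removing the ligand left an empty structure")
    return out
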