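"""Small-molecule model for linear alditols (sugar alcohols).

An alditol is an acyclic HOCH2-(CHOH)n-CH2OH chain; the hexitols handled here
(allitol, sorbitol/D-glucitol) have six carbons, one hydroxyl per carbon and
four internal stereocenters C2..C5. The module builds ideal-geometry 3-D
conformers from a list of CIP descriptors, perceives bonds and backbone for
ligands read from coordinate files, and assigns R/S descriptors from 3-D
chirality (via rdkit).

Numbering convention: backbone carbons are ordered C1..Cn along the chain
(atom names decide when present, otherwise the lower-serial end is C1);
stereo descriptors are reported for the internal carbons C2..C(n-1) in that
order. Sorbitol in this convention is (2S,3R,4R,5R), allitol (2S,3S,4R,5R) —
the C3 epimer pair.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler
from rdkit.Geometry import Point3D

from .geometry import place_atom, tetrahedral_completions, unit
from .structure_io import Atom

__all__ = [
    "LigandMolecule",
    "StereoConfig",
    "BondPerceptionError",
    "SORBITOL",
    "ALLITOL",
    "COVALENT_RADII",
    "build_alditol",
    "stereo_descriptors",
    "perceive_bonds",
    "molecular_formula",
    "ligand_from_atoms",
]

#: single-bond covalent radii, Angstrom (Cordero et al. consensus values)
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}

#: default ideal bond lengths, Angstrom
BOND_LENGTHS = {("C", "C"): 1.54, ("C", "O"): 1.43, ("C", "H"): 1.09, ("O", "H"): 0.96}

TETRA = float(np.arccos(-1.0 / 3.0))  # 109.47 deg


class BondPerceptionError(ValueError):
    """Raised when a consistent bond graph / backbone cannot be perceived."""


@dataclass(frozen=True)
class StereoConfig:
    """Ordered R/S descriptors for the internal carbons of an alditol."""

    descriptors: tuple[str, ...]

    def __post_init__(self):
        # lowercase r/s are the CIP labels of pseudoasymmetric centers (they
        # occur in odd-length alditols, e.g. pentitol C3, not in hexitols)
        if any(d not in ("R", "S", "r", "s") for d in self.descriptors):
            raise ValueError(f"descriptors must be R/S (or r/s), got {self.descriptors}")

    def __len__(self) -> int:
        return len(self.descriptors)

    def flipped_at(self, carbon: int) -> "StereoConfig":
        """Return the epimer config; ``carbon`` is the backbone number (C2 = 2)."""
        i = carbon - 2
        if not 0 <= i < len(self.descriptors):
            raise ValueError(f"carbon {carbon} is not an internal stereocenter")
        d = list(self.descriptors)
        d[i] = {"R": "S", "S": "R", "r": "s", "s": "r"}[d[i]]
        return StereoConfig(tuple(d))

    def differing_positions(self, other: "StereoConfig") -> list[int]:
        """Backbone carbon numbers at which two configs differ."""
        if len(self) != len(other):
            raise ValueError("configs have different lengths")
        return [i + 2 for i, (a, b) in enumerate(zip(self.descriptors, other.descriptors)) if a != b]


#: D-sorbitol (D-glucitol), (2S,3R,4R,5R)-hexane-1,2,3,4,5,6-hexol
SORBITOL = StereoConfig(("S", "R", "R", "R"))
#: allitol, the C3 epimer of sorbitol (meso)
ALLITOL = SORBITOL.flipped_at(3)


@dataclass
class LigandMolecule:
    """Atoms + covalent bond graph + alditol annotations.

    ``backbone`` holds atom indices of C1..Cn in order; ``hydroxyl_map`` maps a
    backbone carbon index to the index of its bonded hydroxyl oxygen.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    backbone: list[int] = field(default_factory=list)
    hydroxyl_map: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, p in zip(self.atoms, np.asarray(xyz, dtype=float)):
            a.position = p.copy()

    def copy(self) -> "LigandMolecule":
        return LigandMolecule(
            [a.copy() for a in self.atoms],
            list(self.bonds),
            list(self.backbone),
            dict(self.hydroxyl_map),
        )

    def heavy_only(self) -> "LigandMolecule":
        """Drop hydrogens (crystal structures have none); reperceives annotations."""
        heavy = [a.copy() for a in self.atoms if a.element != "H"]
        return ligand_from_atoms(heavy)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def with_het_code(self, code: str) -> "LigandMolecule":
        out = self.copy()
        for a in out.atoms:
            a.residue_name = code
            a.record_kind = "HETATM"
        return out


# ---------------------------------------------------------------------------
# bond / backbone perception
# ---------------------------------------------------------------------------

def perceive_bonds(atoms: list[Atom], *, tolerance: float = 0.45) -> list[tuple[int, int]]:
    """Bond i-j iff distance < r_cov(i) + r_cov(j) + tolerance.

    Raises :class:`BondPerceptionError` if the resulting graph is disconnected.
    """
    n = len(atoms)
    bonds: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            ri = COVALENT_RADII.get(atoms[i].element, 0.77)
            rj = COVALENT_RADII.get(atoms[j].element, 0.77)
            d = np.linalg.norm(atoms[i].position - atoms[j].position)
            if d < ri + rj + tolerance:
                bonds.append((i, j))
    if n > 1:
        seen = {0}
        frontier = [0]
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for a, b in bonds:
            adj[a].append(b)
            adj[b].append(a)
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        if len(seen) != n:
            raise BondPerceptionError(
                f"bond graph disconnected ({len(seen)}/{n} atoms reachable)"
            )
    return bonds


def _longest_carbon_path(atoms: list[Atom], bonds: list[tuple[int, int]]) -> list[int]:
    carbons = [i for i, a in enumerate(atoms) if a.element == "C"]
    adj: dict[int, list[int]] = {i: [] for i in carbons}
    cset = set(carbons)
    for a, b in bonds:
        if a in cset and b in cset:
            adj[a].append(b)
            adj[b].append(a)
    best: list[int] = []

    def dfs(node: int, path: list[int], visited: set[int]):
        nonlocal best
        if len(path) > len(best):
            best = list(path)
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, path, visited)
                path.pop()
                visited.remove(nb)

    for start in carbons:
        dfs(start, [start], {start})
    return best


_CNAME = re.compile(r"^C(\d+)$")


def _annotate(mol: LigandMolecule) -> None:
    """Fill backbone and hydroxyl_map from names when present, else perception."""
    named = {}
    for i, a in enumerate(mol.atoms):
        m = _CNAME.match(a.name.strip())
        if m:
            named[int(m.group(1))] = i
    if named and sorted(named) == list(range(1, len(named) + 1)):
        backbone = [named[k] for k in sorted(named)]
    else:
        backbone = _longest_carbon_path(mol.atoms, mol.bonds)
        if backbone and mol.atoms[backbone[0]].serial > mol.atoms[backbone[-1]].serial:
            backbone = backbone[::-1]
    mol.backbone = backbone
    mol.hydroxyl_map = {}
    for ci in backbone:
        for nb in mol.neighbors(ci):
            if mol.atoms[nb].element == "O":
                mol.hydroxyl_map[ci] = nb
                break


def ligand_from_atoms(atoms: list[Atom], *, tolerance: float = 0.45) -> LigandMolecule:
    """Build a LigandMolecule from bare atoms: perceive bonds, backbone, hydroxyls."""
    mol = LigandMolecule(atoms, perceive_bonds(atoms, tolerance=tolerance))
    _annotate(mol)
    return mol


# ---------------------------------------------------------------------------
# stereo perception (rdkit-backed CIP)
# ---------------------------------------------------------------------------

def _to_rdkit(mol: LigandMolecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j in mol.bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.position)))
    m = rw.GetMol()
    m.AddConformer(conf)
    Chem.SanitizeMol(m)
    return m


def stereo_descriptors(ligand: LigandMolecule) -> StereoConfig:
    """CIP R/S descriptors of the internal backbone carbons, from 3-D chirality."""
    if not ligand.backbone:
        raise BondPerceptionError("ligand has no perceived carbon backbone")
    for ci in ligand.backbone[1:-1]:
        if ci not in ligand.hydroxyl_map:
            raise BondPerceptionError(
                f"backbone carbon index {ci} has no hydroxyl oxygen; not an alditol"
            )
    m = _to_rdkit(ligand)
    Chem.AssignStereochemistryFrom3D(m)
    rdCIPLabeler.AssignCIPLabels(m)
    out = []
    for ci in ligand.backbone[1:-1]:
        atom = m.GetAtomWithIdx(ci)
        code = atom.GetPropsAsDict().get("_CIPCode")
        if code is None:
            raise BondPerceptionError(
                f"no CIP descriptor assignable at backbone carbon index {ci}"
            )
        out.append(code)
    return StereoConfig(tuple(out))


def write_sdf(ligand: LigandMolecule, path) -> None:
    """SDF/MOL export for interoperability with cheminformatics tools."""
    from rdkit.Chem import MolToMolFile

    MolToMolFile(_to_rdkit(ligand), str(path))


def molecular_formula(ligand: LigandMolecule) -> dict[str, int]:
    """Element → count map (e.g. sorbitol → {'C': 6, 'H': 14, 'O': 6})."""
    return dict(Counter(a.element for a in ligand.atoms))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _mk(name: str, element: str, pos: np.ndarray, serial: int, het: str) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element,
        position=np.asarray(pos, float),
        residue_name=het,
        chain_id="L",
        residue_seq=1,
        record_kind="HETATM",
    )


def build_alditol(
    config: StereoConfig,
    *,
    cc: float = BOND_LENGTHS[("C", "C")],
    co: float = BOND_LENGTHS[("C", "O")],
    ch: float = BOND_LENGTHS[("C", "H")],
    oh: float = BOND_LENGTHS[("O", "H")],
    het_code: str = "LIG",
) -> LigandMolecule:
    """Build an ideal-geometry alditol in the extended (all-anti) conformation.

    The backbone is a tetrahedral zigzag; every carbon carries one hydroxyl.
    Each internal center is placed and then verified against ``config`` by CIP
    perception, swapping the O/H substituents when needed, so the returned
    molecule realises the requested descriptors exactly.
    """
    n = len(config) + 2
    if n < 3:
        raise ValueError("need at least one internal carbon")

    # zigzag backbone: C3 placed in-plane, C4.. by NeRF with all-anti torsions
    bb = [np.zeros(3), np.array([cc, 0.0, 0.0])]
    bb.append(place_atom(np.array([0.0, 1.0, 0.0]), bb[0], bb[1], cc, TETRA, 0.0))
    for i in range(3, n):
        bb.append(place_atom(bb[i - 3], bb[i - 2], bb[i - 1], cc, TETRA, np.pi))

    atoms: list[Atom] = []
    serial = 1
    idx_c: list[int] = []
    for i, p in enumerate(bb):
        atoms.append(_mk(f"C{i + 1}", "C", p, serial, het_code))
        idx_c.append(len(atoms) - 1)
        serial += 1

    def add(name, element, pos):
        nonlocal serial
        atoms.append(_mk(name, element, pos, serial, het_code))
        serial += 1
        return len(atoms) - 1

    o_idx: dict[int, int] = {}
    h_on_c: dict[int, list[int]] = {}
    # terminal carbons: O anti to the second-next backbone carbon, two Hs flanking
    for term, inner, ref in ((0, 1, 2), (n - 1, n - 2, n - 3)):
        c, nb = bb[term], bb[inner]
        o = place_atom(bb[ref], nb, c, co, TETRA, np.pi)
        oi = add(f"O{term + 1}", "O", o)
        o_idx[term] = oi
        h1 = place_atom(bb[ref], nb, c, ch, TETRA, np.pi / 3)
        h2 = place_atom(bb[ref], nb, c, ch, TETRA, -np.pi / 3)
        h_on_c[term] = [add(f"H{term + 1}A", "H", h1), add(f"H{term + 1}B", "H", h2)]
    # internal carbons: fill the two free tetrahedral slots with O and H
    for i in range(1, n - 1):
        d1, d2 = tetrahedral_completions(bb[i], bb[i - 1], bb[i + 1])
        oi = add(f"O{i + 1}", "O", bb[i] + co * d1)
        o_idx[i] = oi
        h_on_c[i] = [add(f"H{i + 1}", "H", bb[i] + ch * d2)]
    # hydroxyl hydrogens, anti to the backbone
    for i in range(n):
        o = atoms[o_idx[i]].position
        hpos = place_atom(bb[i - 1] if i > 0 else bb[i + 1], bb[i], o, oh, np.deg2rad(107.0), np.pi)
        add(f"HO{i + 1}", "H", hpos)

    mol = LigandMolecule(atoms, perceive_bonds(atoms))
    _annotate(mol)

    # fix each internal center to the requested descriptor by swapping O <-> H
    # (case-insensitive: a pseudoasymmetric center answers 'r' to a request
    # for 'R'; the O/H swap toggles it exactly like a normal center)
    got = stereo_descriptors(mol)
    for k, (want, have) in enumerate(zip(config.descriptors, got.descriptors)):
        if want.upper() != have.upper():
            ci = k + 1  # backbone position index (0-based) of C(k+2)
            oi = o_idx[ci]
            hi = h_on_c[ci][0]
            c = bb[ci]
            do = unit(atoms[oi].position - c)
            dh = unit(atoms[hi].position - c)
            atoms[oi].position = c + co * dh
            atoms[hi].position = c + ch * do
            # re-seat the hydroxyl hydrogen on the moved oxygen
            ho = next(a for a in atoms if a.name == f"HO{ci + 1}")
            ho.position = place_atom(bb[ci - 1], c, atoms[oi].position, oh, np.deg2rad(107.0), np.pi)
    mol = LigandMolecule(atoms, perceive_bonds(atoms))
    _annotate(mol)
    final = stereo_descriptors(mol)
    if tuple(d.upper() for d in final.descriptors) != tuple(
        d.upper() for d in config.descriptors
    ):
        raise BondPerceptionError(
            f"stereo construction failed: wanted {config.descriptors}, got {final.descriptors}"
        )
    return mol
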