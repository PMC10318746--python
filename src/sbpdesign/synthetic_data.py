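"""Analytic synthetic fixtures: pockets with planted polar contacts, clashes
and designable gain-of-contact sites, plus homodimers and stereoisomer pairs.

All geometry is planted by construction (contact atoms placed on a sphere of
the target radius around a chosen ligand oxygen, along the extended C-O bond
direction so the antecedent-angle criterion holds trivially), never by
minimization — the ground truth is therefore exact and every generated
fixture is re-verified against the analysis operations before it is returned.

These fixtures emulate the *layout* of a solute-binding-protein pocket (a
shell of the residue chemotypes seen in real alditol pockets around a bound
hexitol), not a real protein fold: residues are disconnected single units
with ideal geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_analysis import ContactCriteria, polar_contacts, residues_within
from .geometry import rotation_about_axis, unit
from .ligand_model import ALLITOL, SORBITOL, LigandMolecule, StereoConfig, build_alditol
from .residue_templates import N_CHI, build_residue
from .structure_io import Atom, StructureModel

__all__ = [
    "FixtureSpec",
    "GenerationError",
    "make_pocket",
    "make_dimer",
    "make_stereo_pair",
]


class GenerationError(RuntimeError):
    """Planted geometry could not be realised (overlaps / infeasible spec)."""


#: primary polar side-chain atom used as the planted contact atom
CONTACT_ATOMS = {
    "SER": "OG",
    "THR": "OG1",
    "TYR": "OH",
    "CYS": "SG",
    "ASN": "ND2",
    "GLN": "NE2",
    "ASP": "OD1",
    "GLU": "OE1",
    "HIS": "ND1",
    "LYS": "NZ",
    "ARG": "NH1",
    "TRP": "NE1",
}

#: atom planted at the target distance for non-polar spectator residues
SPECTATOR_ATOMS = {"PHE": "CZ", "VAL": "CG1", "LEU": "CD1", "ILE": "CD1", "ALA": "CB", "PRO": "CG", "GLY": "CA"}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic pocket.

    ``contacts``: (residue identity, donor-acceptor target distance A) —
    each plants exactly one protein-ligand polar bond.
    ``spectators``: (identity, min-distance A) — residues planted in or near
    the pocket that cannot form polar bonds (or are beyond the polar window).
    ``clash``: optional (identity, distance A) planting a side-chain atom
    inside the repulsive wall of a ligand atom.
    ``designable_site``: optional (identity-that-gains, chi1 deg, distance A):
    plants an ALA whose backbone is positioned so that mutating it to the
    given identity at the given chi1 creates one new polar bond.
    """

    seed: int = 0
    ligand: str = "allitol"
    het_code: str = "X9X"
    contacts: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("HIS", 2.9),
            ("ARG", 2.9),
            ("ARG", 3.0),
            ("ASP", 2.8),
            ("GLN", 3.1),
        ]
    )
    spectators: list[tuple[str, float]] = field(
        default_factory=lambda: [("PHE", 3.5), ("VAL", 3.8)]
    )
    clash: tuple[str, float] | None = None
    designable_site: tuple[str, float, float] | None = None
    dimerize: bool = False
    jitter: float = 0.0  # A, optional random perturbation of planted atoms

    def __post_init__(self):
        for _, d in self.contacts:
            if not (2.4 <= d <= 10.0):
                raise ValueError(f"planted distance {d} outside [2.4, 10] A")


def _ligand_config(name: str) -> StereoConfig:
    try:
        return {"allitol": ALLITOL, "sorbitol": SORBITOL}[name]
    except KeyError:
        raise ValueError(f"unknown ligand {name!r} (use 'allitol' or 'sorbitol')")


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping direction a onto direction b."""
    a, b = unit(a), unit(b)
    c = float(a @ b)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, perp))
        return rotation_about_axis(axis, np.pi)
    axis = np.cross(a, b)
    return rotation_about_axis(axis, float(np.arccos(np.clip(c, -1, 1))))


def _plant_residue(
    resname: str,
    planted_atom: str,
    target_point: np.ndarray,
    outward: np.ndarray,
    seq: int,
    *,
    chis: tuple[float, ...] | None = None,
    chain_id: str = "A",
) -> list[Atom]:
    """Build a residue and rigidly place it so ``planted_atom`` sits at
    ``target_point`` with the rest of the residue pointing along ``outward``."""
    if chis is None:
        chis = (180.0,) * N_CHI[resname]
    atoms = build_residue(resname, chis=chis, chain_id=chain_id, residue_seq=seq)
    by_name = {a.name: a for a in atoms}
    if planted_atom not in by_name:
        raise GenerationError(f"{resname} has no atom {planted_atom!r}")
    t = by_name[planted_atom].position
    # orient the planted atom's interaction direction (anti to the mean of its
    # covalent-neighbour directions, i.e. its lone-pair/H direction) toward the
    # ligand anchor, so every antecedent angle opens well past 90 degrees
    from .ligand_model import COVALENT_RADII

    r0 = COVALENT_RADII.get(by_name[planted_atom].element, 0.77)
    nbr_dirs = []
    for a in atoms:
        if a.name == planted_atom:
            continue
        r1 = COVALENT_RADII.get(a.element, 0.77)
        d = np.linalg.norm(a.position - t)
        if d < r0 + r1 + 0.45:
            nbr_dirs.append(unit(a.position - t))
    if nbr_dirs:
        inward = np.sum(nbr_dirs, axis=0)
    else:
        inward = np.mean([a.position for a in atoms], axis=0) - t
    if np.linalg.norm(inward) < 1e-6:
        inward = np.mean([a.position for a in atoms], axis=0) - t
    R = _align_rotation(inward, outward)
    for a in atoms:
        a.position = R @ (a.position - t) + target_point
    return atoms


def _roll_for_clearance(
    atoms: list[Atom],
    pivot: np.ndarray,
    axis: np.ndarray,
    placed: list[Atom],
    step_deg: float = 30.0,
) -> None:
    """Roll a planted residue about its planting axis to maximise the minimum
    distance to already-placed residues.

    The axis passes through the planted atom and the ligand anchor, so the
    planted distance and both antecedent angles are invariant under the roll.
    """
    if not placed:
        return
    placed_xyz = np.array([a.position for a in placed])
    best_angle, best_clearance = 0.0, -np.inf
    for k in range(int(round(360.0 / step_deg))):
        theta = np.deg2rad(k * step_deg)
        R = rotation_about_axis(axis, theta)
        xyz = np.array([R @ (a.position - pivot) + pivot for a in atoms])
        d = np.min(
            np.linalg.norm(xyz[:, None, :] - placed_xyz[None, :, :], axis=-1)
        )
        if d > best_clearance + 1e-9:
            best_angle, best_clearance = theta, d
    if best_angle != 0.0:
        R = rotation_about_axis(axis, best_angle)
        for a in atoms:
            a.position = R @ (a.position - pivot) + pivot


def _anchor_directions(ligand: LigandMolecule):
    """Iterator of (oxygen position, outward unit vector) planting slots.

    One radial slot per hydroxyl (along the extended C->O bond, so the
    ligand-side antecedent angle is 180 deg by construction), then extra
    slots off the two chain ends tilted along the chain axis. The slots are
    geometrically disjoint, so planted residues do not collide."""
    base = []
    for ci in ligand.backbone:
        oi = ligand.hydroxyl_map.get(ci)
        if oi is None:
            continue
        c, o = ligand.atoms[ci].position, ligand.atoms[oi].position
        base.append((o, unit(o - c)))
    if not base:
        raise GenerationError("ligand has no hydroxyl oxygens to anchor on")
    tangent = unit(
        ligand.atoms[ligand.backbone[-1]].position - ligand.atoms[ligand.backbone[0]].position
    )
    slots = list(base)
    # overflow slots: off the two chain ends, tilted away from the terminal
    # hydroxyl so they stay clear of the radially planted residues
    c_first = ligand.atoms[ligand.backbone[0]].position
    c_last = ligand.atoms[ligand.backbone[-1]].position
    _, u0 = base[0]
    _, un = base[-1]
    slots.append((c_first, unit(-tangent - 0.6 * u0)))
    slots.append((c_last, unit(tangent - 0.6 * un)))

    def gen():
        for s in slots:
            yield s
        raise GenerationError(
            f"fixture needs more than {len(slots)} planted entities; not supported"
        )

    return gen()


def make_pocket(
    spec: FixtureSpec,
    criteria: ContactCriteria | None = None,
) -> tuple[StructureModel, LigandMolecule, dict]:
    """Build a pocket fixture and its analytic ground truth.

    Returns (model, ligand, ground_truth); the model contains the protein
    residues plus the ligand as HETATM records. Ground truth keys:
    ``pocket_residues`` (within the neighbor cutoff), ``contact_residues``,
    ``n_contacts``, ``planted`` (per-entity detail) and, when a designable
    site is planted, ``designable`` with the gain recipe.
    """
    criteria = criteria or ContactCriteria()
    rng = np.random.default_rng(spec.seed)
    ligand = build_alditol(_ligand_config(spec.ligand), het_code=spec.het_code).heavy_only()
    ligand = ligand.with_het_code(spec.het_code)
    for a in ligand.atoms:
        a.chain_id = "A"
        a.residue_seq = 500
    anchors = _anchor_directions(ligand)

    entities: list[tuple[list[Atom], np.ndarray, np.ndarray]] = []
    protein_atoms: list[Atom] = []
    planted: list[dict] = []
    expected_contact_residues: list[tuple[str, int, str]] = []
    expected_pocket: set[tuple[str, int, str]] = set()
    seq = 10

    def jitterv():
        if spec.jitter <= 0:
            return np.zeros(3)
        return rng.normal(scale=spec.jitter / np.sqrt(3.0), size=3)

    for resname, dist in spec.contacts:
        if resname not in CONTACT_ATOMS:
            raise GenerationError(f"no contact-atom rule for {resname!r}")
        o_pos, u = next(anchors)
        target = o_pos + dist * u + jitterv()
        atoms = _plant_residue(resname, CONTACT_ATOMS[resname], target, u, seq)
        entities.append((atoms, target, u))
        protein_atoms.extend(atoms)
        key = ("A", seq, resname)
        planted.append({"residue": key, "kind": "contact", "distance": dist})
        expected_contact_residues.append(key)
        if dist <= criteria.neighbor_cutoff:
            expected_pocket.add(key)
        seq += 10

    ground: dict = {}
    if spec.designable_site is not None:
        gain_res, chi1, dist = spec.designable_site
        if gain_res not in CONTACT_ATOMS or N_CHI[gain_res] < 1:
            raise GenerationError(f"designable identity {gain_res!r} cannot gain a contact")
        o_pos, u = next(anchors)
        target = o_pos + dist * u
        chis = (chi1,) + (180.0,) * (N_CHI[gain_res] - 1)
        gain_atoms = _plant_residue(
            gain_res, CONTACT_ATOMS[gain_res], target, u, seq, chis=chis
        )
        # keep only the backbone + CB: the placed site is an ALA whose backbone
        # admits the gain identity/rotamer by construction
        keep = {"N", "CA", "C", "O", "CB"}
        site_atoms = [a for a in gain_atoms if a.name in keep]
        for a in site_atoms:
            a.residue_name = "ALA"
        entities.append((site_atoms, target, u))
        protein_atoms.extend(site_atoms)
        key = ("A", seq, "ALA")
        planted.append({"residue": key, "kind": "designable", "distance": dist})
        ground["designable"] = {
            "residue": key,
            "gain_identity": gain_res,
            "gain_chi1": chi1,
            "distance": dist,
        }
        seq += 10


    for resname, dist in spec.spectators:
        atom_name = SPECTATOR_ATOMS.get(resname)
        if atom_name is None:
            raise GenerationError(f"no spectator-atom rule for {resname!r}")
        o_pos, u = next(anchors)
        target = o_pos + dist * u + jitterv()
        atoms = _plant_residue(resname, atom_name, target, u, seq)
        entities.append((atoms, target, u))
        protein_atoms.extend(atoms)
        key = ("A", seq, resname)
        planted.append({"residue": key, "kind": "spectator", "distance": dist})
        seq += 10

    if spec.clash is not None:
        resname, dist = spec.clash
        atom_name = SPECTATOR_ATOMS.get(resname, CONTACT_ATOMS.get(resname))
        o_pos, u = next(anchors)
        target = o_pos + dist * u
        atoms = _plant_residue(resname, atom_name, target, u, seq, chis=(180.0,) * N_CHI[resname])
        entities.append((atoms, target, u))
        protein_atoms.extend(atoms)
        key = ("A", seq, resname)
        planted.append({"residue": key, "kind": "clash", "distance": dist})
        seq += 10

    # global roll relaxation: coordinate ascent on inter-entity clearance.
    # Rolling about the planting axis leaves every planted distance and
    # antecedent angle invariant, so the analytic ground truth is unaffected.
    for _ in range(3):
        for k, (atoms, pivot, axis) in enumerate(entities):
            others = list(ligand.atoms) + [
                a for j, (ats, _, _) in enumerate(entities) if j != k for a in ats
            ]
            _roll_for_clearance(atoms, pivot, axis, others, step_deg=15.0)

    # pocket membership from the final coordinates, by the brute-force
    # all-pairs definition (planted anchor distances are exact by design;
    # other atoms may sit closer after rolling, so measure, don't assume)
    lig_xyz = np.array([a.position for a in ligand.atoms])
    for info, (atoms, _, _) in zip(planted, entities):
        xyz = np.array([a.position for a in atoms])
        min_d = float(
            np.min(np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1))
        )
        info["min_distance"] = min_d
        if min_d <= criteria.neighbor_cutoff:
            expected_pocket.add(info["residue"])

    model = StructureModel([a.copy() for a in protein_atoms])
    model.extend(a.copy() for a in ligand.atoms)
    model.renumber_serials()

    # residue-residue overlap sanity (planted clash exempt, it clashes with the ligand)
    res = model.residues()
    keys = [k for k in res if not all(a.is_hetero for a in res[k])]
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = min(
                np.linalg.norm(a.position - b.position)
                for a in res[keys[i]]
                for b in res[keys[j]]
            )
            if d < 2.0:
                raise GenerationError(
                    f"planted residues {keys[i]} and {keys[j]} overlap (min {d:.2f} A)"
                )

    ground.update(
        {
            "planted": planted,
            "contact_residues": expected_contact_residues,
            "n_contacts": len(expected_contact_residues),
            "pocket_residues": sorted(expected_pocket, key=lambda k: k[1]),
        }
    )

    # generation/analysis consistency check (skipped for deliberate clashes,
    # which may sit inside the polar window with bad geometry)
    if spec.clash is None and spec.jitter <= 0.05:
        found = polar_contacts(model, ligand, criteria)
        got = sorted({c.residue for c in found}, key=lambda k: k[1])
        want = sorted(set(expected_contact_residues), key=lambda k: k[1])
        if len(found) != ground["n_contacts"] or got != want:
            raise GenerationError(
                f"planted contacts not recovered: expected {want} "
                f"({ground['n_contacts']}), analysis found {got} ({len(found)})"
            )
        got_pocket = residues_within(model, ligand, criteria.neighbor_cutoff)
        if got_pocket != ground["pocket_residues"]:
            raise GenerationError(
                f"pocket mismatch: expected {ground['pocket_residues']}, got {got_pocket}"
            )
    return model, ligand, ground


def make_dimer(spec: FixtureSpec, *, separation: float = 25.0) -> StructureModel:
    """Duplicate the pocket monomer as chain B, each chain with its own ligand.

    Chain B is the monomer rotated half a turn about z and translated along x
    so the two chains are at least ~`separation` A apart, emulating the
    two-identical-monomers layout of the crystal dimer.
    """
    model, _, _ = make_pocket(spec)
    span = np.ptp(model.coords, axis=0).max()
    shift = np.array([span + separation, 0.0, 0.0])
    Rz = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)
    dimer = model.copy()
    for a in model.atoms:
        b = a.copy()
        b.chain_id = "B"
        b.position = Rz @ a.position + shift
        dimer.atoms.append(b)
    dimer.renumber_serials()
    return dimer


def make_stereo_pair(
    position: int = 3,
) -> tuple[LigandMolecule, LigandMolecule]:
    """(reference-like, target-like) hexitols differing at exactly one center.

    For the default position 3 this is the allitol/sorbitol pair; other
    positions give the corresponding epimer of sorbitol.
    """
    if not 2 <= position <= 5:
        raise ValueError("hexitol stereocenters are C2..C5")
    target = SORBITOL
    reference = target.flipped_at(position)
    ref_code = "X9X" if reference == ALLITOL else "EPI"
    return (
        build_alditol(reference, het_code=ref_code),
        build_alditol(target, het_code="SOR"),
    )
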