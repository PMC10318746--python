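"""Place an epimer ligand in a binding pocket by backbone superposition.

The docking recipe is purely geometric: (1) least-squares (Kabsch) rigid
superposition of the six-carbon backbone of the new ligand onto the bound
reference ligand, (2) torsional refinement rotating C-C bonds so the hydroxyl
oxygens match their reference counterparts — excluding the hydroxyl on the
epimeric carbon, whose configuration differs by construction — and (3)
iteration of (1)+(2) to convergence, then swapping the old ligand out of the
complex. No receptor flexibility and no physics: pose quality is inherited
from the crystal pose of the reference ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import rotation_about_axis, unit
from .ligand_model import LigandMolecule
from .structure_io import StructureModel

__all__ = [
    "RigidTransform",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "refine_hydroxyl_torsions",
    "dock_by_backbone",
    "swap_ligand",
]


class DegenerateGeometryError(ValueError):
    """Fewer than three non-collinear correspondence pairs."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation least-squares superposition (Kabsch, SVD form).

    ``mobile`` and ``reference`` are (n, 3) arrays in correspondence order
    (row i of one pairs with row i of the other). Returns the transform
    minimising RMSD over all rigid motions and that minimal RMSD. Reflections
    are explicitly excluded — an improper transform would invert the ligand's
    stereochemistry.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 correspondence pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered mobile set
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("correspondence points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _rotatable_bonds(mol: LigandMolecule) -> list[tuple[int, int, list[int]]]:
    """Backbone C-C bonds with the set of atoms distal to each bond.

    Rotating bond (Ci, Ci+1) moves everything on the Ci+1 side. Returned as
    (pivot_a, pivot_b, moving_atom_indices).
    """
    out = []
    bb = mol.backbone
    adj: dict[int, list[int]] = {i: mol.neighbors(i) for i in range(len(mol.atoms))}
    for k in range(len(bb) - 1):
        a, b = bb[k], bb[k + 1]
        # atoms reachable from b without crossing the a-b bond
        seen = {a, b}
        frontier = [b]
        moving = []
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    moving.append(nb)
                    frontier.append(nb)
        out.append((a, b, moving))
    return out


def _hydroxyl_objective(
    mol: LigandMolecule, ref: LigandMolecule, skip_backbone_pos: int | None
) -> float:
    """Summed squared deviation of hydroxyl oxygens from reference, Angstrom^2."""
    total = 0.0
    for k, (ci, ri) in enumerate(zip(mol.backbone, ref.backbone)):
        if skip_backbone_pos is not None and k == skip_backbone_pos - 1:
            continue
        if ci in mol.hydroxyl_map and ri in ref.hydroxyl_map:
            d = mol.atoms[mol.hydroxyl_map[ci]].position - ref.atoms[ref.hydroxyl_map[ri]].position
            total += float(d @ d)
    return total


def _best_angle_about_axis(
    points: np.ndarray, targets: np.ndarray, origin: np.ndarray, axis: np.ndarray
) -> float:
    """Closed-form angle minimising sum |R(theta) p - q|^2 about a fixed axis.

    Decomposing each point into axial and radial parts, the objective is
    K - (B cos t + C sin t); the minimiser is atan2(C, B).
    """
    k = unit(axis)
    B = 0.0
    C = 0.0
    for p, q in zip(points - origin, targets - origin):
        p_par = (p @ k) * k
        p_perp = p - p_par
        q_eff = q - p_par
        B += float(p_perp @ q_eff)
        C += float(np.cross(k, p_perp) @ q_eff)
    if abs(B) < 1e-15 and abs(C) < 1e-15:
        return 0.0
    return float(np.arctan2(C, B))


def refine_hydroxyl_torsions(
    placed: LigandMolecule,
    reference: LigandMolecule,
    *,
    excluded_carbon: int | None = 3,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> LigandMolecule:
    """Cyclic coordinate descent over backbone C-C torsions.

    Minimises the summed squared deviation of hydroxyl oxygens from their
    reference counterparts, skipping the hydroxyl on ``excluded_carbon``
    (1-based backbone numbering; C3 by default — the epimeric position). Each
    1-D subproblem has the closed form solved by :func:`_best_angle_about_axis`;
    a move is kept only if the global objective does not increase, so the
    objective is non-increasing across sweeps.
    """
    if not placed.hydroxyl_map or not reference.hydroxyl_map:
        raise ValueError("both ligands need a hydroxyl_map (are these alditols?)")
    mol = placed.copy()
    bonds = _rotatable_bonds(mol)
    obj = _hydroxyl_objective(mol, reference, excluded_carbon)
    for _ in range(max_sweeps):
        start = obj
        for a, b, moving in bonds:
            if not moving:
                continue
            # oxygens in the objective that actually move with this bond
            sel_pts, sel_tgt = [], []
            moving_set = set(moving)
            for k, (ci, ri) in enumerate(zip(mol.backbone, reference.backbone)):
                if excluded_carbon is not None and k == excluded_carbon - 1:
                    continue
                oi = mol.hydroxyl_map.get(ci)
                rj = reference.hydroxyl_map.get(ri)
                if oi is None or rj is None or oi not in moving_set:
                    continue
                sel_pts.append(mol.atoms[oi].position)
                sel_tgt.append(reference.atoms[rj].position)
            if not sel_pts:
                continue
            origin = mol.atoms[a].position
            axis = mol.atoms[b].position - origin
            theta = _best_angle_about_axis(
                np.array(sel_pts), np.array(sel_tgt), origin, axis
            )
            R = rotation_about_axis(axis, theta)
            trial = mol.copy()
            for mi in moving:
                trial.atoms[mi].position = origin + R @ (trial.atoms[mi].position - origin)
            trial_obj = _hydroxyl_objective(trial, reference, excluded_carbon)
            if trial_obj <= obj:
                mol, obj = trial, trial_obj
        if start - obj < tol:
            break
    return mol


def dock_by_backbone(
    new_ligand: LigandMolecule,
    reference_ligand: LigandMolecule,
    *,
    excluded_carbon: int | None = 3,
    rmsd_tol: float = 1e-4,
    max_rounds: int = 50,
) -> tuple[LigandMolecule, dict]:
    """Alternate backbone superposition and hydroxyl torsion refinement.

    Both backbone correspondence directions (C1->C1 and C1->C6) are scored on
    the first superposition and the lower-RMSD orientation kept, since chain
    numbering direction is convention-dependent. Iterates until the backbone
    RMSD changes by less than ``rmsd_tol`` between rounds. Returns the placed
    ligand and a log dict with per-round RMSD values.
    """
    if len(new_ligand.backbone) != len(reference_ligand.backbone):
        raise ValueError(
            f"backbone length mismatch: {len(new_ligand.backbone)} vs "
            f"{len(reference_ligand.backbone)}"
        )
    mob = new_ligand.copy()
    ref_xyz_f = np.array([reference_ligand.atoms[i].position for i in reference_ligand.backbone])
    mob_bb = lambda m: np.array([m.atoms[i].position for i in m.backbone])

    # choose correspondence direction
    tf_f, r_f = kabsch_superpose(mob_bb(mob), ref_xyz_f)
    tf_r, r_r = kabsch_superpose(mob_bb(mob)[::-1], ref_xyz_f)
    if r_r < r_f:
        mob.backbone = mob.backbone[::-1]
        tf, rmsd = tf_r, r_r
    else:
        tf, rmsd = tf_f, r_f
    mob.set_coords(tf.apply(mob.coords))

    log = {"rounds": [], "reversed": bool(r_r < r_f)}
    prev = np.inf
    for rnd in range(max_rounds):
        mob = refine_hydroxyl_torsions(
            mob, reference_ligand, excluded_carbon=excluded_carbon
        )
        tf, rmsd = kabsch_superpose(mob_bb(mob), ref_xyz_f)
        mob.set_coords(tf.apply(mob.coords))
        log["rounds"].append(
            {
                "round": rnd + 1,
                "backbone_rmsd": rmsd,
                "hydroxyl_obj": _hydroxyl_objective(mob, reference_ligand, excluded_carbon),
            }
        )
        if abs(prev - rmsd) < rmsd_tol:
            break
        prev = rmsd
    return mob, log


def swap_ligand(
    complex_model: StructureModel,
    old_code: str,
    new_ligand: LigandMolecule,
    *,
    new_code: str = "SOR",
    chain: str | None = None,
) -> StructureModel:
    """Replace the bound ligand: complex - old het group + placed new ligand.

    The new ligand must already be in the pocket frame (see
    :func:`dock_by_backbone`). Protein atoms are untouched; the new ligand is
    appended as HETATM records with fresh serials, inheriting the old ligand's
    chain id and residue number.
    """
    from .structure_io import remove_ligand, _het_residue_atoms

    old_atoms = _het_residue_atoms(complex_model, old_code, chain)
    old_chain, old_seq = old_atoms[0].chain_id, old_atoms[0].residue_seq
    out = remove_ligand(complex_model, old_code, chain=chain)
    for a in new_ligand.atoms:
        na = a.copy()
        na.record_kind = "HETATM"
        na.residue_name = new_code
        na.chain_id = old_chain
        na.residue_seq = old_seq
        out.atoms.append(na)
    out.renumber_serials()
    return out
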