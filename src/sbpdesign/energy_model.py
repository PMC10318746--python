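"""Reduced all-heavy-atom scoring model.

A deliberately small, fully specified stand-in for a macromolecular
scorefunction, in dimensionless reduced energy units (REU-like):

* Lennard-Jones 12-6 with per-element parameters (Lorentz-Berthelot mixing),
  10 A cutoff and a smooth 8-10 A switching function;
* Coulomb with template partial charges and a distance-dependent dielectric
  eps(r) = D*r (D = 4), same cutoff/switch;
* a square-well hydrogen-bond term: -1 reduced unit per geometric polar
  contact (the same criteria used for contact reporting, so design pressure
  and the polar-bond bookkeeping agree);
* a 3-fold torsion penalty over bonded quadruples.

1-2 and 1-3 pairs are excluded, 1-4 pairs scaled by 0.5. Absolute values are
meaningful only within this model; only differences (and the ddG cycle built
from them) are interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .contact_analysis import ContactCriteria, _protein_polar_roles, _ligand_polar_roles
from .geometry import bond_angle
from .ligand_model import COVALENT_RADII
from .residue_templates import RESIDUE_BONDS
from .structure_io import StructureModel

__all__ = [
    "EnergyBreakdown",
    "ForceFieldParams",
    "ParameterizationError",
    "default_params",
    "model_topology",
    "score",
    "score_parts",
]


class ParameterizationError(ValueError):
    """An atom could not be assigned LJ/charge parameters."""


@dataclass
class EnergyBreakdown:
    lj: float = 0.0
    coulomb: float = 0.0
    hbond: float = 0.0
    torsion: float = 0.0

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.hbond + self.torsion

    def as_dict(self) -> dict[str, float]:
        return {
            "lj": self.lj,
            "coulomb": self.coulomb,
            "hbond": self.hbond,
            "torsion": self.torsion,
            "total": self.total,
        }


@dataclass
class ForceFieldParams:
    """Parsed parameter set; see ``data/reduced_ff.params`` for the format."""

    lj: dict[str, tuple[float, float]] = field(default_factory=dict)  # element -> (sigma, eps)
    charges: dict[tuple[str, str], float] = field(default_factory=dict)  # (resname|*, atom) -> q
    het_element_charges: dict[str, float] = field(default_factory=dict)
    het_polar_carbon_charge: float = 0.4
    dielectric_slope: float = 4.0
    coulomb_constant: float = 332.0637
    cutoff: float = 10.0
    switch_start: float = 8.0
    scale_14: float = 0.5
    hbond_well_depth: float = 1.0
    torsion_barrier: float = 0.10
    lj_repulsive_scale: float = 1.0  # ramped during relax

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceFieldParams":
        p = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            key = tok[0]
            if key == "LJ":
                p.lj[tok[1]] = (float(tok[2]), float(tok[3]))
            elif key == "CHARGE":
                p.charges[(tok[1], tok[2])] = float(tok[3])
            elif key == "HETCHARGE":
                p.het_element_charges[tok[1]] = float(tok[2])
            elif key == "HETC_POLAR":
                p.het_polar_carbon_charge = float(tok[1])
            elif key in (
                "DIELECTRIC_SLOPE",
                "COULOMB_CONSTANT",
                "CUTOFF",
                "SWITCH_START",
                "SCALE_14",
                "HBOND_WELL_DEPTH",
                "TORSION_BARRIER",
            ):
                setattr(p, key.lower(), float(tok[1]))
            else:
                raise ParameterizationError(f"unknown parameter line: {raw!r}")
        return p

    def with_repulsive_scale(self, s: float) -> "ForceFieldParams":
        import copy

        q = copy.copy(self)
        q.lj_repulsive_scale = s
        return q


def default_params() -> ForceFieldParams:
    ref = resources.files("sbpdesign").joinpath("data/reduced_ff.params")
    with resources.as_file(ref) as path:
        return ForceFieldParams.from_file(path)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def model_topology(model: StructureModel) -> list[tuple[int, int]]:
    """Covalent bonds as atom-index pairs.

    Protein residues use the template bond lists plus peptide C(i)-N(i+1)
    links; het groups are perceived by covalent-radius distance within the
    group. Non-bonded inter-residue contacts never become bonds, so planted
    clashes stay repulsive.
    """
    bonds: list[tuple[int, int]] = []
    index_of = {id(a): i for i, a in enumerate(model.atoms)}
    residues = list(model.residues().items())
    name_maps = []
    for key, atoms in residues:
        name_maps.append({a.name: a for a in atoms})
    for (key, atoms), names in zip(residues, name_maps):
        if all(a.is_hetero for a in atoms):
            for i in range(len(atoms)):
                for j in range(i + 1, len(atoms)):
                    ri = COVALENT_RADII.get(atoms[i].element, 0.77)
                    rj = COVALENT_RADII.get(atoms[j].element, 0.77)
                    if np.linalg.norm(atoms[i].position - atoms[j].position) < ri + rj + 0.45:
                        bonds.append((index_of[id(atoms[i])], index_of[id(atoms[j])]))
        else:
            template = RESIDUE_BONDS.get(key[2])
            if template is None:
                # unknown residue type: distance perception within the residue
                for i in range(len(atoms)):
                    for j in range(i + 1, len(atoms)):
                        ri = COVALENT_RADII.get(atoms[i].element, 0.77)
                        rj = COVALENT_RADII.get(atoms[j].element, 0.77)
                        if np.linalg.norm(atoms[i].position - atoms[j].position) < ri + rj + 0.45:
                            bonds.append((index_of[id(atoms[i])], index_of[id(atoms[j])]))
            else:
                for a_name, b_name in template:
                    if a_name in names and b_name in names:
                        bonds.append(
                            (index_of[id(names[a_name])], index_of[id(names[b_name])])
                        )
    # peptide bonds between consecutive residues of the same chain
    for ((k1, a1), n1), ((k2, a2), n2) in zip(
        zip(residues, name_maps), zip(residues[1:], name_maps[1:])
    ):
        if k1[0] != k2[0] or any(a.is_hetero for a in a1) or any(a.is_hetero for a in a2):
            continue
        if k2[1] - k1[1] == 1 and "C" in n1 and "N" in n2:
            if np.linalg.norm(n1["C"].position - n2["N"].position) < 2.0:
                bonds.append((index_of[id(n1["C"])], index_of[id(n2["N"])]))
    return bonds


def _exclusions(n: int, bonds: list[tuple[int, int]]) -> dict[tuple[int, int], float]:
    """Pair -> scale factor: 0 for 1-2/1-3, scale_14 placeholder 0.5-coded as -1.

    Returns {pair: 0.0} for excluded and {pair: -1.0} for 1-4 (caller applies
    the configured 1-4 factor)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out: dict[tuple[int, int], float] = {}
    for a, b in bonds:
        out[(min(a, b), max(a, b))] = 0.0
    for j in range(n):
        nbrs = sorted(adj[j])
        for x in nbrs:
            for y in nbrs:
                if x < y:
                    out.setdefault((x, y), 0.0)
    # 1-4: paths of length 3
    for a, b in bonds:
        for x in adj[a]:
            if x in (a, b):
                continue
            for y in adj[b]:
                if y in (a, b) or y == x:
                    continue
                key = (min(x, y), max(x, y))
                out.setdefault(key, -1.0)
    return out


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def _assign(model: StructureModel, params: ForceFieldParams, bonds):
    adj: dict[int, list[int]] = {i: [] for i in range(len(model.atoms))}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    sigma = np.empty(len(model.atoms))
    eps = np.empty(len(model.atoms))
    q = np.zeros(len(model.atoms))
    for i, a in enumerate(model.atoms):
        if a.element not in params.lj:
            raise ParameterizationError(
                f"no LJ parameters for element {a.element!r} (atom {a.serial} {a.name})"
            )
        sigma[i], eps[i] = params.lj[a.element]
        if a.is_hetero:
            if a.element in params.het_element_charges:
                q[i] = params.het_element_charges[a.element]
            elif a.element == "C" and any(
                model.atoms[j].element == "O" for j in adj[i]
            ):
                q[i] = params.het_polar_carbon_charge
        else:
            key = (a.residue_name, a.name)
            if key in params.charges:
                q[i] = params.charges[key]
            elif ("*", a.name) in params.charges:
                q[i] = params.charges[("*", a.name)]
    return sigma, eps, q


def _switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """Standard cubic-in-r^2 switching function, 1 below r_on, 0 above r_off."""
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    s = np.ones_like(r)
    mask = r2 > on2
    num = (off2 - r2[mask]) ** 2 * (off2 + 2.0 * r2[mask] - 3.0 * on2)
    s[mask] = num / (off2 - on2) ** 3
    s[r >= r_off] = 0.0
    return s


# ---------------------------------------------------------------------------
# hydrogen-bond proxy within a whole model
# ---------------------------------------------------------------------------

def _hbond_count(
    model: StructureModel,
    bonds: list[tuple[int, int]],
    criteria: ContactCriteria,
) -> int:
    """Count geometric polar contacts between atoms of different residues."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(model.atoms))}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    polar = []  # (idx, donor, acceptor)
    for i, a in enumerate(model.atoms):
        if a.element == "H":
            continue
        if a.is_hetero:
            d, acc = _ligand_polar_roles(a)
        else:
            d, acc = _protein_polar_roles(a, criteria)
        if d or acc:
            polar.append((i, d, acc))
    if not polar:
        return 0
    xyz = np.array([model.atoms[i].position for i, _, _ in polar])
    tree = cKDTree(xyz)
    count = 0
    pairs = tree.query_pairs(r=criteria.polar_distance_max)
    for pi, pj in pairs:
        i, di, acci = polar[pi]
        j, dj, accj = polar[pj]
        ai, aj = model.atoms[i], model.atoms[j]
        if (ai.chain_id, ai.residue_seq) == (aj.chain_id, aj.residue_seq):
            continue
        if not ((di and accj) or (dj and acci)):
            continue
        d = float(np.linalg.norm(ai.position - aj.position))
        if d < criteria.polar_distance_min:
            continue
        ok = True
        for x in adj[i]:
            if model.atoms[x].element == "H":
                continue
            if np.rad2deg(bond_angle(model.atoms[x].position, ai.position, aj.position)) < criteria.angle_min:
                ok = False
                break
        if ok:
            for x in adj[j]:
                if model.atoms[x].element == "H":
                    continue
                if np.rad2deg(bond_angle(model.atoms[x].position, aj.position, ai.position)) < criteria.angle_min:
                    ok = False
                    break
        if ok:
            count += 1
    return count


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(
    model: StructureModel,
    params: ForceFieldParams | None = None,
    *,
    criteria: ContactCriteria | None = None,
    brute_force: bool = False,
) -> EnergyBreakdown:
    """Score a structure with the reduced model. Deterministic for fixed input.

    ``brute_force=True`` replaces the neighbor-list pair search by the O(N^2)
    double loop (used as an independent oracle in tests).
    """
    params = params or default_params()
    criteria = criteria or ContactCriteria()
    if len(model.atoms) == 0:
        raise ValueError("cannot score an empty model")
    bonds = model_topology(model)
    sigma, eps, q = _assign(model, params, bonds)
    xyz = model.coords
    n = len(model.atoms)
    excl = _exclusions(n, bonds)

    if brute_force:
        pair_list = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        tree = cKDTree(xyz)
        pair_list = sorted(tree.query_pairs(r=params.cutoff))

    # exclusion filtering and 1-4 scaling
    kept: list[tuple[int, int]] = []
    factors: list[float] = []
    for i, j in pair_list:
        scale = excl.get((i, j))
        if scale == 0.0:
            continue
        kept.append((i, j))
        factors.append(params.scale_14 if scale == -1.0 else 1.0)

    e_lj = 0.0
    e_coul = 0.0
    if kept:
        ii = np.fromiter((p[0] for p in kept), dtype=int)
        jj = np.fromiter((p[1] for p in kept), dtype=int)
        fac = np.asarray(factors)
        d = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
        if np.any(d < 1e-9):
            k = int(np.argmin(d))
            raise ValueError(f"coincident atoms {ii[k]} and {jj[k]}")
        live = d < params.cutoff
        ii, jj, fac, d = ii[live], jj[live], fac[live], d[live]
        sw = _switch(d, params.switch_start, params.cutoff)
        s = 0.5 * (sigma[ii] + sigma[jj])
        e = np.sqrt(eps[ii] * eps[jj])
        sr6 = (s / d) ** 6
        e_lj = float(
            np.sum(fac * sw * 4.0 * e * (params.lj_repulsive_scale * sr6 * sr6 - sr6))
        )
        qq = q[ii] * q[jj]
        e_coul = float(
            np.sum(
                fac
                * sw
                * params.coulomb_constant
                * qq
                / (params.dielectric_slope * d * d)
            )
        )

    e_hb = -params.hbond_well_depth * _hbond_count(model, bonds, criteria)

    # 3-fold torsion penalty over bonded quadruples, batch-evaluated
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    quads: list[tuple[int, int, int, int]] = []
    for b1, b2 in bonds:
        for a in adj[b1]:
            if a == b2:
                continue
            for d4 in adj[b2]:
                if d4 == b1 or d4 == a:
                    continue
                quads.append((a, b1, b2, d4))
    e_tor = 0.0
    if quads:
        qarr = np.array(quads)
        p0, p1, p2, p3 = (xyz[qarr[:, k]] for k in range(4))
        b0 = p1 - p0
        b1v = p2 - p1
        b2v = p3 - p2
        n1 = np.cross(b0, b1v)
        n2 = np.cross(b1v, b2v)
        b1n = b1v / np.linalg.norm(b1v, axis=1, keepdims=True)
        m1 = np.cross(n1, b1n)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        phi = np.arctan2(y, x)
        e_tor = float(np.sum(params.torsion_barrier * (1.0 + np.cos(3.0 * phi))))

    return EnergyBreakdown(lj=float(e_lj), coulomb=float(e_coul), hbond=float(e_hb), torsion=float(e_tor))


def score_parts(
    complex_model: StructureModel,
    ligand_code: str,
    params: ForceFieldParams | None = None,
    *,
    criteria: ContactCriteria | None = None,
) -> tuple[float, float, float]:
    """(G_C, G_P, G_L): complex, apo protein, and free ligand total energies,
    all under identical parameters — the inputs of the binding cycle."""
    from .structure_io import remove_ligand, _het_residue_atoms

    params = params or default_params()
    lig_atoms = _het_residue_atoms(complex_model, ligand_code, None)
    g_c = score(complex_model, params, criteria=criteria).total
    apo = remove_ligand(complex_model, ligand_code)
    g_p = score(apo, params, criteria=criteria).total
    lig_model = StructureModel([a.copy() for a in lig_atoms])
    g_l = score(lig_model, params, criteria=criteria).total
    return g_c, g_p, g_l
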