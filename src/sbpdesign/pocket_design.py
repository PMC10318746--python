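"""Fixed-backbone pocket redesign: Metropolis simulated-annealing packing over
residue identities and rotamers, plus torsion-space minimization and a
repack/minimize "relax" protocol.

Moves replace side-chain heavy atoms only; backbone N-CA-C-O stay at their
input coordinates. Residue modes follow the resfile convention: NATRO (do not
touch), NATAA (native identity, repack rotamers), ALLAA (any identity, any
rotamer). All stochastic operations are driven by an explicit seed and are
bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy_model import ForceFieldParams, default_params, score
from .geometry import rotation_about_axis
from .residue_templates import (
    AMINO_ACIDS,
    N_CHI,
    RESIDUE_BONDS,
    build_side_chain,
)
from .structure_io import Atom, StructureModel

__all__ = [
    "DesignSpec",
    "AnnealingSchedule",
    "RotamerLibrary",
    "mutate_residue",
    "metropolis_step",
    "pack",
    "minimize",
    "relax",
    "repeat_optimize",
    "sidechain_torsions",
]

ResKey = tuple[str, int, str]  # (chain, seq, name)


# ---------------------------------------------------------------------------
# design spec (resfile analogue)
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Per-residue design mode table.

    ``modes`` maps (chain, residue_seq) to NATRO/NATAA/ALLAA; unlisted
    residues get ``default_mode``.
    """

    modes: dict[tuple[str, int], str] = field(default_factory=dict)
    default_mode: str = "NATRO"
    #: optional identity restriction per residue (resfile PIKAA analogue);
    #: only consulted for ALLAA residues
    allowed: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    _VALID = ("NATRO", "NATAA", "ALLAA")

    def __post_init__(self):
        for k, v in self.modes.items():
            if v not in self._VALID:
                raise ValueError(f"invalid mode {v!r} for residue {k}")
        if self.default_mode not in self._VALID:
            raise ValueError(f"invalid default mode {self.default_mode!r}")

    def mode_of(self, chain: str, seq: int) -> str:
        return self.modes.get((chain, seq), self.default_mode)

    def validate_against(self, model: StructureModel) -> None:
        present = {(k[0], k[1]) for k in model.residues() if k[2] in RESIDUE_BONDS}
        missing = [k for k in self.modes if k not in present]
        if missing:
            raise LookupError(f"design spec names absent residues: {missing}")

    @classmethod
    def from_resfile(cls, path: str | Path) -> "DesignSpec":
        """Parse ``DEFAULT <mode>`` header plus ``<resnum> <chain> <mode>`` lines."""
        default = "NATRO"
        modes: dict[tuple[str, int], str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0].upper() == "DEFAULT":
                default = tok[1].upper()
            else:
                modes[(tok[1], int(tok[0]))] = tok[2].upper()
        return cls(modes, default)


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule for the packing walk."""

    kT_start: float = 100.0
    kT_end: float = 0.3
    n_steps: int | None = None  # default: 50 per designable residue
    seed: int = 0

    def __post_init__(self):
        if not (self.kT_start >= self.kT_end > 0):
            raise ValueError("need kT_start >= kT_end > 0")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("need at least one step")

    def temperatures(self, n_designable: int) -> np.ndarray:
        n = self.n_steps if self.n_steps is not None else 50 * max(1, n_designable)
        if n == 1:
            return np.array([self.kT_start])
        ratio = (self.kT_end / self.kT_start) ** (1.0 / (n - 1))
        return self.kT_start * ratio ** np.arange(n)


class RotamerLibrary:
    """Coarse chi-angle library: every rotatable chi sampled at -60/60/180.

    Proline gets its two canonical ring puckers instead (the chi values that
    approximately close the pyrrolidine ring).
    """

    CHI_VALUES = (-60.0, 60.0, 180.0)
    SPECIAL = {"PRO": [(-25.0, 35.0), (25.0, -35.0)]}

    def __init__(self, chi_values: tuple[float, ...] | None = None):
        self.chi_values = tuple(chi_values or self.CHI_VALUES)
        self._cache: dict[str, list[tuple[float, ...]]] = {}

    def rotamers(self, resname: str) -> list[tuple[float, ...]]:
        if resname not in N_CHI:
            raise KeyError(f"no rotamers for unknown residue {resname!r}")
        if resname in self.SPECIAL:
            return list(self.SPECIAL[resname])
        if resname not in self._cache:
            n = N_CHI[resname]
            self._cache[resname] = (
                [()] if n == 0 else [t for t in itertools.product(self.chi_values, repeat=n)]
            )
        return self._cache[resname]


# ---------------------------------------------------------------------------
# structural moves
# ---------------------------------------------------------------------------

def _backbone_atoms(res_atoms: list[Atom]) -> dict[str, Atom]:
    bb = {a.name: a for a in res_atoms if a.name in ("N", "CA", "C", "O")}
    for req in ("N", "CA", "C"):
        if req not in bb:
            raise ValueError(
                f"residue {res_atoms[0].chain_id}{res_atoms[0].residue_seq} lacks backbone atom {req}"
            )
    return bb


def mutate_residue(
    model: StructureModel,
    key: tuple[str, int],
    new_resname: str,
    chis: tuple[float, ...],
) -> StructureModel:
    """Replace one residue's side chain (and identity) at fixed backbone."""
    if new_resname not in RESIDUE_BONDS:
        raise KeyError(f"unknown target residue type {new_resname!r}")
    out = StructureModel()
    done = False
    for res_key, res_atoms in model.residues().items():
        if (res_key[0], res_key[1]) != key:
            out.extend(a.copy() for a in res_atoms)
            continue
        done = True
        bb = _backbone_atoms(res_atoms)
        new_atoms = []
        for name in ("N", "CA", "C", "O"):
            if name in bb:
                a = bb[name].copy()
                a.residue_name = new_resname
                new_atoms.append(a)
        side = build_side_chain(
            new_resname,
            bb["N"].position,
            bb["CA"].position,
            bb["C"].position,
            chis,
        )
        for name, element, pos in side:
            new_atoms.append(
                Atom(
                    serial=0,
                    name=name,
                    element=element,
                    position=pos,
                    residue_name=new_resname,
                    chain_id=res_key[0],
                    residue_seq=res_key[1],
                    record_kind="ATOM",
                )
            )
        out.extend(new_atoms)
    if not done:
        raise LookupError(f"residue {key} not found")
    out.renumber_serials()
    return out


def metropolis_step(
    current_energy: float, proposal_energy: float, kT: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion: accept downhill always, uphill with exp(-dE/kT)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    d_e = proposal_energy - current_energy
    if d_e <= 0:
        return True
    return bool(rng.random() < math.exp(-d_e / kT))


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def _designable(model: StructureModel, spec: DesignSpec) -> list[tuple[ResKey, str]]:
    """(residue key, mode) for residues the spec allows to move."""
    out = []
    for res_key in model.residues():
        if res_key[2] not in RESIDUE_BONDS:
            continue
        mode = spec.mode_of(res_key[0], res_key[1])
        if mode in ("NATAA", "ALLAA"):
            out.append((res_key, mode))
    return out


def _choices_for(
    mode: str, native: str, library: RotamerLibrary, allowed: list[str] | None = None
):
    if mode == "ALLAA":
        identities = sorted(allowed) if allowed else sorted(AMINO_ACIDS)
    else:
        identities = [native]
    out = []
    for aa in identities:
        rots = library.rotamers(aa)
        if not rots:
            raise LookupError(f"no rotamers for {aa}")
        for ri, chis in enumerate(rots):
            out.append((aa, ri, chis))
    return out


def pack(
    complex_model: StructureModel,
    spec: DesignSpec,
    schedule: AnnealingSchedule | None = None,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
    *,
    exhaustive: bool = False,
) -> tuple[StructureModel, list[dict]]:
    """Metropolis simulated-annealing walk over (identity, rotamer) assignments.

    Returns the best-ever structure and a trajectory log. With
    ``exhaustive=True`` the full assignment space is enumerated instead (only
    sensible for small problems; used as its own oracle in testing). Ties are
    broken toward the lexicographically smallest (identity, rotamer index)
    assignment for reproducibility.
    """
    schedule = schedule or AnnealingSchedule()
    library = library or RotamerLibrary()
    params = params or default_params()
    spec.validate_against(complex_model)
    design = _designable(complex_model, spec)
    log: list[dict] = []
    if not design:
        return complex_model.copy(), log

    choice_sets = {
        key: _choices_for(mode, key[2], library, spec.allowed.get((key[0], key[1])))
        for key, mode in design
    }

    def apply_assignment(model, assignment):
        cur = model
        for key, (aa, _ri, chis) in assignment.items():
            cur = mutate_residue(cur, (key[0], key[1]), aa, chis)
        return cur

    if exhaustive:
        keys = [key for key, _ in design]
        best = None
        for combo in itertools.product(*(choice_sets[k] for k in keys)):
            assignment = dict(zip(keys, combo))
            cand = apply_assignment(complex_model, assignment)
            e = score(cand, params).total
            tag = tuple((c[0], c[1]) for c in combo)
            if best is None or (e, tag) < (best[0], best[2]):
                best = (e, cand, tag, assignment)
        log.append({"mode": "exhaustive", "best_energy": best[0]})
        return best[1], log

    rng = np.random.default_rng(schedule.seed)
    # start from native identities at native-ish chis: keep input side chains
    current = complex_model.copy()
    current_energy = score(current, params).total
    assignment: dict[ResKey, tuple[str, int, tuple[float, ...]]] = {}
    best_model, best_energy = current.copy(), current_energy
    temps = schedule.temperatures(len(design))
    keys = [key for key, _ in design]
    for step, kT in enumerate(temps):
        key = keys[rng.integers(len(keys))]
        choices = choice_sets[key]
        aa, ri, chis = choices[rng.integers(len(choices))]
        trial_assignment = dict(assignment)
        trial_assignment[key] = (aa, ri, chis)
        trial = apply_assignment(complex_model, trial_assignment)
        trial_energy = score(trial, params).total
        accepted = metropolis_step(current_energy, trial_energy, kT, rng)
        if accepted:
            current, current_energy, assignment = trial, trial_energy, trial_assignment
            if current_energy < best_energy - 1e-12:
                best_model, best_energy = current.copy(), current_energy
        log.append(
            {
                "step": step,
                "kT": float(kT),
                "residue": key,
                "proposal": (aa, ri),
                "energy": trial_energy,
                "accepted": accepted,
                "best": best_energy,
            }
        )
    return best_model, log


# ---------------------------------------------------------------------------
# torsion-space minimization
# ---------------------------------------------------------------------------

def sidechain_torsions(model: StructureModel) -> list[tuple[tuple[int, int, int, int], list[int]]]:
    """Rotatable side-chain chi torsions as (atom index quadruple, moving set).

    Ring chis (PRO, and the chi2/chi3 of rings handled as rigid groups) are
    included only where rotating them moves a chain tail, i.e. the standard
    chi definitions over template parent paths.
    """
    out = []
    index_of = {id(a): i for i, a in enumerate(model.atoms)}
    for res_key, res_atoms in model.residues().items():
        resname = res_key[2]
        if resname not in RESIDUE_BONDS or resname == "PRO":
            continue
        names = {a.name: a for a in res_atoms}
        # chain of chi-defining atoms: N, CA, CB, then first chi-tied atom per level
        chain = ["N", "CA", "CB"]
        if "CB" not in names:
            continue
        from .residue_templates import SIDECHAIN_TEMPLATES

        chi_tips: dict[int, str] = {}
        for name, _el, _par, _l, _a, tors in SIDECHAIN_TEMPLATES[resname]:
            if tors[0] == "chi" and tors[2] == 0.0:
                chi_tips[tors[1]] = name
        for k in sorted(chi_tips):
            chain.append(chi_tips[k])
        for k in range(len(chain) - 3):
            quad_names = chain[k : k + 4]
            if any(n not in names for n in quad_names):
                break
            quad = tuple(index_of[id(names[n])] for n in quad_names)
            # moving: all side-chain atoms distal to the rotated bond
            axis_c = quad_names[2]
            order = ["CB"] + [rec[0] for rec in SIDECHAIN_TEMPLATES[resname]]
            start = order.index(axis_c)
            moving = [
                index_of[id(names[n])]
                for n in order[start + 1 :]
                if n in names
            ]
            if moving:
                out.append((quad, moving))
    return out


def minimize(
    complex_model: StructureModel,
    movable: list[tuple[tuple[int, int, int, int], list[int]]] | None = None,
    params: ForceFieldParams | None = None,
    *,
    tolerance: float = 1e-4,
    max_sweeps: int = 20,
    coarse_deg: float = 15.0,
) -> StructureModel:
    """Cyclic coordinate descent over torsions; energy never increases.

    Each torsion is line-searched on a coarse grid plus parabolic refinement;
    a move is applied only if it lowers the total energy. ``movable`` defaults
    to all side-chain chi torsions.
    """
    params = params or default_params()
    model = complex_model.copy()
    e0 = score(model, params).total
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy")
    if movable is None:
        movable = sidechain_torsions(model)
    energy = e0
    for _ in range(max_sweeps):
        start = energy
        for quad, moving in movable:
            xyz = model.coords
            origin = xyz[quad[1]]
            axis = xyz[quad[2]] - origin
            if np.linalg.norm(axis) < 1e-9:
                continue
            best_theta, best_e = 0.0, energy
            grid = np.deg2rad(np.arange(-180.0, 180.0, coarse_deg))
            for theta in grid:
                if abs(theta) < 1e-12:
                    continue
                trial = model.copy()
                R = rotation_about_axis(axis, float(theta))
                txyz = trial.coords
                for mi in moving:
                    txyz[mi] = origin + R @ (txyz[mi] - origin)
                trial.set_coords(txyz)
                e = score(trial, params).total
                if e < best_e:
                    best_theta, best_e = float(theta), e
            if best_theta != 0.0:
                # parabolic refinement around the grid optimum
                h = np.deg2rad(coarse_deg)
                es = []
                for theta in (best_theta - h, best_theta, best_theta + h):
                    trial = model.copy()
                    R = rotation_about_axis(axis, float(theta))
                    txyz = trial.coords
                    for mi in moving:
                        txyz[mi] = origin + R @ (txyz[mi] - origin)
                    trial.set_coords(txyz)
                    es.append(score(trial, params).total)
                denom = es[0] - 2 * es[1] + es[2]
                theta_ref = best_theta
                if abs(denom) > 1e-12:
                    theta_ref = best_theta - 0.5 * h * (es[2] - es[0]) / denom
                cand_thetas = {best_theta, theta_ref}
                for theta in cand_thetas:
                    trial = model.copy()
                    R = rotation_about_axis(axis, float(theta))
                    txyz = trial.coords
                    for mi in moving:
                        txyz[mi] = origin + R @ (txyz[mi] - origin)
                    trial.set_coords(txyz)
                    e = score(trial, params).total
                    if e < energy:
                        model, energy = trial, e
        if start - energy < tolerance:
            break
    return model


# ---------------------------------------------------------------------------
# relax / repeat protocols
# ---------------------------------------------------------------------------

def relax(
    complex_model: StructureModel,
    n_cycles: int = 2,
    params: ForceFieldParams | None = None,
    *,
    repulsive_ramp: tuple[float, ...] = (0.2, 0.6, 1.0),
    seed: int = 0,
) -> StructureModel:
    """Repack-and-minimize protocol with a ramped LJ repulsive term.

    Each cycle runs, at increasing repulsive scale, a NATAA repack of every
    standard residue followed by side-chain torsion minimization. The
    best-energy structure at full repulsion is kept; the best-seen energy is
    monotone non-increasing across cycles.
    """
    params = params or default_params()
    model = complex_model.copy()
    spec = DesignSpec(default_mode="NATAA")
    best = model.copy()
    best_e = score(best, params).total
    for cycle in range(n_cycles):
        for stage, s in enumerate(repulsive_ramp):
            stage_params = params.with_repulsive_scale(s)
            sched = AnnealingSchedule(
                kT_start=10.0, kT_end=0.3, seed=seed + 1000 * cycle + stage
            )
            model, _ = pack(model, spec, sched, params=stage_params)
            model = minimize(model, params=stage_params, max_sweeps=2, coarse_deg=30.0)
        e = score(model, params).total
        if e < best_e:
            best, best_e = model.copy(), e
    return best


def repeat_optimize(
    complex_model: StructureModel,
    kT: float = 1.0,
    n: int = 20,
    seed: int = 0,
    params: ForceFieldParams | None = None,
) -> StructureModel:
    """n independent fixed-temperature Metropolis repack sweeps; best kept.

    The preset (kT = 1, n = 20) mirrors the iterated-optimization stage of
    the original workflow.
    """
    params = params or default_params()
    spec = DesignSpec(default_mode="NATAA")
    best = complex_model.copy()
    best_e = score(best, params).total
    for i in range(n):
        sched = AnnealingSchedule(kT_start=kT, kT_end=kT, seed=seed + i)
        cand, _ = pack(complex_model, spec, sched, params=params)
        e = score(cand, params).total
        if e < best_e:
            best, best_e = cand, e
    return best
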