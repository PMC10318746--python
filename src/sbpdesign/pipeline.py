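"""End-to-end workflow driver.

Stage order (file nicknames follow the crystal-dimer provenance lineage):
protein.pdb -> proall.pdb (monomer + bound ligand) -> sorbitol.pdb (built
epimer) -> prosor.pdb (docked swap) -> finprosor.pdb (selective design),
minprosor.pdb (torsion minimization), fastprosor.pdb (relax). Contacts are
reported before design, after design and after relax; the ddG cycle pairs
the *pre-minimization* wild-type energies with the designed-state energies —
minimizing the wild type first would bias G_P and corrupt the cycle, so the
driver enforces that pairing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .contact_analysis import ContactCriteria, contact_report, polar_contacts, residues_within
from .energy_model import default_params, score, score_parts
from .ligand_model import build_alditol, stereo_descriptors
from .pocket_design import (
    AnnealingSchedule,
    DesignSpec,
    minimize,
    pack,
    relax,
)
from .pocket_docking import dock_by_backbone, swap_ligand
from .structure_io import extract_ligand, extract_monomer, read_pdb, write_pdb
from .synthetic_data import FixtureSpec, make_dimer
from .thermo_cycle import ThermodynamicCycle, cycle_report, ddg_bind, is_favorable

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("sbpdesign.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    input_pdb: Path | None = None  # None -> synthetic dimer preset
    out_dir: Path = Path("pipeline_out")
    chain: str | None = None  # None -> first protein chain
    ligand_code: str = "X9X"
    new_code: str = "SOR"
    epimer_position: int = 3
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    resfile: Path | None = None  # None -> auto: zero-contact pocket residues
    seed: int = 0
    design_steps: int | None = None
    relax_cycles: int = 1

    def validate(self) -> None:
        if self.input_pdb is not None and not Path(self.input_pdb).exists():
            raise FileNotFoundError(self.input_pdb)
        if self.resfile is not None and not Path(self.resfile).exists():
            raise FileNotFoundError(self.resfile)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full redesign workflow; returns (and writes) the manifest."""
    config.validate()
    current = {"stage": "init"}

    def _stage(name: str) -> None:
        current["stage"] = name
        log.info("[%s] start", name)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = default_params()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "criteria": {
            "neighbor_cutoff": config.criteria.neighbor_cutoff,
            "polar_distance_max": config.criteria.polar_distance_max,
            "polar_distance_min": config.criteria.polar_distance_min,
            "angle_min": config.criteria.angle_min,
        },
        "files": {},
        "scores": {},
    }

    def emit(nickname: str, model) -> None:
        path = out / f"{nickname}.pdb"
        write_pdb(model, path)
        manifest["files"][nickname] = str(path)

    try:
        # ---- prepare -----------------------------------------------------
        _stage("prepare")
        if config.input_pdb is None:
            protein = make_dimer(FixtureSpec(seed=config.seed))
        else:
            protein = read_pdb(config.input_pdb)
        emit("protein", protein)
        chain = config.chain or protein.chain_ids[0]
        proall = extract_monomer(protein, chain)
        emit("proall", proall)
        crystal_ligand = extract_ligand(proall, config.ligand_code)
        from .structure_io import StructureModel

        emit("allitol", StructureModel([a.copy() for a in crystal_ligand.atoms]))

        # ---- build the epimer ligand ------------------------------------
        _stage("build-ligand")
        ref_config = stereo_descriptors(crystal_ligand)
        new_config = ref_config.flipped_at(config.epimer_position)
        new_ligand = build_alditol(new_config, het_code=config.new_code).heavy_only()
        emit("sorbitol", StructureModel([a.copy() for a in new_ligand.atoms]))

        # ---- dock + swap -------------------------------------------------
        _stage("dock")
        placed, dock_log = dock_by_backbone(
            new_ligand, crystal_ligand, excluded_carbon=config.epimer_position
        )
        manifest["dock"] = {
            "rounds": len(dock_log["rounds"]),
            "final_backbone_rmsd": dock_log["rounds"][-1]["backbone_rmsd"],
            "reversed_correspondence": dock_log["reversed"],
        }
        prosor = swap_ligand(proall, config.ligand_code, placed, new_code=config.new_code)
        emit("prosor", prosor)
        docked_ligand = extract_ligand(prosor, config.new_code)

        # ---- contacts before design -------------------------------------
        _stage("contacts-before")
        pocket = residues_within(prosor, docked_ligand, config.criteria.neighbor_cutoff)
        before = polar_contacts(prosor, docked_ligand, config.criteria)
        manifest["pocket_size"] = len(pocket)
        manifest["pocket_residues"] = [list(k) for k in pocket]

        # ---- wild-type scores (PRE-minimization, by contract) ------------
        _stage("score-wildtype")
        g_c, g_p, g_l = score_parts(prosor, config.new_code, params, criteria=config.criteria)
        manifest["scores"]["G_C"] = g_c
        manifest["scores"]["G_P"] = g_p
        manifest["scores"]["G_L"] = g_l

        # ---- design ------------------------------------------------------
        _stage("design")
        if config.resfile is not None:
            spec = DesignSpec.from_resfile(config.resfile)
        else:
            # selective design: pocket residues with zero polar bonds
            bonded = {c.residue for c in before}
            modes = {
                (k[0], k[1]): "ALLAA"
                for k in pocket
                if k not in bonded
            }
            spec = DesignSpec(modes=modes, default_mode="NATRO")
        manifest["design_modes"] = {f"{c}{s}": m for (c, s), m in spec.modes.items()}
        sched = AnnealingSchedule(seed=config.seed, n_steps=config.design_steps)
        finprosor, _traj = pack(prosor, spec, sched, params=params)
        emit("finprosor", finprosor)
        g_c_star, g_p_star, _ = score_parts(
            finprosor, config.new_code, params, criteria=config.criteria
        )
        manifest["scores"]["G_C_star"] = g_c_star
        manifest["scores"]["G_P_star"] = g_p_star
        mutated_ligand = extract_ligand(finprosor, config.new_code)
        after = polar_contacts(finprosor, mutated_ligand, config.criteria)

        # ---- minimize / relax variants ----------------------------------
        _stage("minimize")
        minprosor = minimize(prosor, params=params, max_sweeps=2)
        emit("minprosor", minprosor)
        manifest["scores"]["minprosor"] = score(minprosor, params).total

        _stage("relax")
        fastprosor = relax(
            finprosor, n_cycles=config.relax_cycles, params=params, seed=config.seed
        )
        emit("fastprosor", fastprosor)
        manifest["scores"]["fastprosor"] = score(fastprosor, params).total
        relaxed_ligand = extract_ligand(fastprosor, config.new_code)
        after_relax = polar_contacts(fastprosor, relaxed_ligand, config.criteria)

        # ---- contact report ---------------------------------------------
        report = contact_report(
            {
                "before mutation": before,
                "after mutation": after,
                "after relax": after_relax,
            },
            pocket_residues=pocket,
        )
        report_path = out / "contacts.tsv"
        report.to_csv(report_path, sep="\t")
        manifest["files"]["contacts"] = str(report_path)
        manifest["contacts"] = {
            col: int(report.loc["TOTAL", col]) for col in report.columns
        }

        # ---- ddG cycle ---------------------------------------------------
        _stage("ddg")
        cycle = ThermodynamicCycle(
            G_C=g_c, G_P=g_p, G_C_star=g_c_star, G_P_star=g_p_star, G_L=g_l
        )
        ddg = ddg_bind(cycle)
        manifest["ddg"] = ddg
        manifest["verdict"] = is_favorable(ddg)
        table = cycle_report(
            {
                "G_C": g_c,
                "G_P": g_p,
                "G_C*": g_c_star,
                "G_P*": g_p_star,
                "G_L": g_l,
            }
        )
        table_path = out / "cycle.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        manifest["files"]["cycle"] = str(table_path)
    except Exception as exc:
        manifest["failed_stage"] = current["stage"]
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: ddG = %.3f (%s)", ddg, manifest["verdict"])
    return manifest
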