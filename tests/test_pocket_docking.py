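"""Backbone superposition, hydroxyl torsion refinement, ligand swap."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sbpdesign.geometry import rotation_about_axis
from sbpdesign.ligand_model import SORBITOL, build_alditol, stereo_descriptors
from sbpdesign.pocket_docking import (
    DegenerateGeometryError,
    dock_by_backbone,
    kabsch_superpose,
    refine_hydroxyl_torsions,
    swap_ligand,
)
from sbpdesign.structure_io import extract_ligand, read_pdb, write_pdb
from sbpdesign.synthetic_data import make_stereo_pair


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        P = rng.normal(size=(6, 3))
        tf, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_known_transform(self, rng):
        P = rng.normal(size=(8, 3))
        R = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 0.77)
        t = np.array([4.0, -1.0, 2.5])
        tf, rmsd = kabsch_superpose(P, P @ R.T + t)
        assert rmsd < 1e-8
        assert np.allclose(tf.rotation, R, atol=1e-8)
        assert np.allclose(tf.translation, t, atol=1e-8)

    def test_always_proper_rotation_even_for_mirrored_reference(self, rng):
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflected target tempts an improper solution
        tf, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_beats_random_transform_sampling_oracle(self, rng):
        # optimality: no sampled rigid transform does better on noisy data
        P = rng.normal(size=(6, 3))
        R = rotation_about_axis(np.array([0.3, 1.0, -0.5]), 1.2)
        Q = P @ R.T + np.array([1.0, 2.0, 3.0]) + rng.normal(scale=0.3, size=(6, 3))
        _, best = kabsch_superpose(P, Q)
        sample_R = Rotation.random(10_000, random_state=1).as_matrix()
        Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
        moved = np.einsum("nij,kj->nki", sample_R, Pc)
        rmsds = np.sqrt(np.mean(np.sum((moved - Qc) ** 2, axis=-1), axis=-1))
        assert best <= rmsds.min() + 1e-12

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, rng.normal(size=(5, 3)))

    def test_agrees_with_scipy_align_vectors(self, rng):
        P = rng.normal(size=(7, 3))
        Q = rng.normal(size=(7, 3))
        tf, rmsd = kabsch_superpose(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
        assert np.allclose(tf.rotation, rot.as_matrix(), atol=1e-6)


class TestRefineHydroxyls:
    def test_self_refinement_is_identity(self):
        mol = build_alditol(SORBITOL).heavy_only()
        out = refine_hydroxyl_torsions(mol, mol)
        assert np.allclose(out.coords, mol.coords, atol=1e-9)

    def test_single_torsion_matches_grid_oracle(self):
        ref = build_alditol(SORBITOL).heavy_only()
        start = ref.copy()
        # rotate only the terminal C5-C6 bond away from the reference
        from sbpdesign.pocket_docking import _rotatable_bonds, _hydroxyl_objective

        a, b, moving = _rotatable_bonds(start)[-1]
        origin = start.atoms[a].position
        axis = start.atoms[b].position - origin
        R = rotation_about_axis(axis, np.deg2rad(95.0))
        for mi in moving:
            start.atoms[mi].position = origin + R @ (start.atoms[mi].position - origin)

        refined = refine_hydroxyl_torsions(start, ref, excluded_carbon=None)
        got = _hydroxyl_objective(refined, ref, None)

        # brute-force 0.5-degree grid over the same torsion
        best = np.inf
        for deg in np.arange(-180.0, 180.0, 0.5):
            trial = start.copy()
            Rg = rotation_about_axis(axis, np.deg2rad(deg))
            for mi in moving:
                trial.atoms[mi].position = origin + Rg @ (
                    trial.atoms[mi].position - origin
                )
            best = min(best, _hydroxyl_objective(trial, ref, None))
        assert got <= best + 1e-6

    def test_excluded_carbon_not_in_objective(self):
        ref = build_alditol(SORBITOL).heavy_only()
        mol = build_alditol(SORBITOL).heavy_only()
        out1 = refine_hydroxyl_torsions(mol, ref, excluded_carbon=3)
        # perturb only the reference O3: the refinement must not change
        ref2 = ref.copy()
        o3 = ref2.hydroxyl_map[ref2.backbone[2]]
        ref2.atoms[o3].position = ref2.atoms[o3].position + np.array([0.7, -0.4, 0.2])
        out2 = refine_hydroxyl_torsions(mol, ref2, excluded_carbon=3)
        assert np.allclose(out1.coords, out2.coords, atol=1e-12)

    def test_requires_hydroxyl_map(self):
        mol = build_alditol(SORBITOL).heavy_only()
        bare = mol.copy()
        bare.hydroxyl_map = {}
        with pytest.raises(ValueError):
            refine_hydroxyl_torsions(bare, mol)


class TestDockByBackbone:
    def test_self_dock_zero_displacement(self):
        mol = build_alditol(SORBITOL).heavy_only()
        placed, log = dock_by_backbone(mol, mol)
        assert len(log["rounds"]) >= 1
        assert np.allclose(placed.coords, mol.coords, atol=1e-6)

    def test_epimer_dock_backbone_rmsd_below_half_angstrom(self):
        ref, new = make_stereo_pair(3)
        placed, log = dock_by_backbone(new.heavy_only(), ref.heavy_only())
        assert log["rounds"][-1]["backbone_rmsd"] < 0.5

    def test_objective_non_increasing_over_rounds(self):
        ref, new = make_stereo_pair(3)
        _, log = dock_by_backbone(new.heavy_only(), ref.heavy_only())
        rmsds = [r["backbone_rmsd"] for r in log["rounds"]]
        assert all(b <= a + 1e-9 for a, b in zip(rmsds, rmsds[1:]))

    def test_stereochemistry_preserved_by_docking(self):
        ref, new = make_stereo_pair(3)
        newh = new.heavy_only()
        before = stereo_descriptors(newh).descriptors
        placed, _ = dock_by_backbone(newh, ref.heavy_only())
        assert stereo_descriptors(placed).descriptors == before

    def test_backbone_length_mismatch(self):
        from sbpdesign.ligand_model import StereoConfig

        hexitol = build_alditol(SORBITOL).heavy_only()
        tetritol = build_alditol(StereoConfig(("R", "R"))).heavy_only()
        with pytest.raises(ValueError):
            dock_by_backbone(tetritol, hexitol)


class TestSwapLigand:
    def test_counts_after_swap(self, default_pocket):
        model, ligand, _ = default_pocket
        new = build_alditol(SORBITOL, het_code="SOR").heavy_only()
        placed, _ = dock_by_backbone(new, ligand)
        swapped = swap_ligand(model, "X9X", placed, new_code="SOR")
        n_protein = sum(not a.is_hetero for a in model.atoms)
        assert sum(not a.is_hetero for a in swapped.atoms) == n_protein
        assert sum(a.is_hetero for a in swapped.atoms) == len(placed.atoms)
        assert all(
            a.residue_name == "SOR" for a in swapped.atoms if a.is_hetero
        )

    def test_swapping_ligand_for_itself_is_identity(self, default_pocket):
        model, ligand, _ = default_pocket
        swapped = swap_ligand(model, "X9X", ligand.copy(), new_code="X9X")
        assert len(swapped) == len(model)
        assert np.allclose(
            np.sort(swapped.coords, axis=0), np.sort(model.coords, axis=0)
        )

    def test_swapped_complex_round_trips(self, tmp_path, default_pocket):
        model, ligand, _ = default_pocket
        new = build_alditol(SORBITOL, het_code="SOR").heavy_only()
        placed, _ = dock_by_backbone(new, ligand)
        swapped = swap_ligand(model, "X9X", placed, new_code="SOR")
        p = tmp_path / "prosor.pdb"
        write_pdb(swapped, p)
        back = read_pdb(p)
        assert np.allclose(back.coords, swapped.coords, atol=1e-3)
        assert len(extract_ligand(back, "SOR").atoms) == len(placed.atoms)

    def test_missing_old_code(self, default_pocket):
        model, ligand, _ = default_pocket
        with pytest.raises(LookupError):
            swap_ligand(model, "ZZZ", ligand)
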