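"""Metropolis packing, torsion minimization, and the relax protocol."""

import math

import numpy as np
import pytest

from sbpdesign.energy_model import score
from sbpdesign.pocket_design import (
    AnnealingSchedule,
    DesignSpec,
    metropolis_step,
    minimize,
    mutate_residue,
    pack,
    relax,
    repeat_optimize,
    sidechain_torsions,
)
from sbpdesign.contact_analysis import polar_contacts
from sbpdesign.structure_io import extract_ligand
from sbpdesign.synthetic_data import FixtureSpec, make_pocket


class TestDesignSpec:
    def test_mode_validation(self):
        with pytest.raises(ValueError):
            DesignSpec(modes={("A", 1): "WHAT"})
        with pytest.raises(ValueError):
            DesignSpec(default_mode="WHAT")

    def test_resfile_round_trip(self, tmp_path):
        rf = tmp_path / "pocket.resfile"
        rf.write_text("DEFAULT NATRO\n10 A ALLAA\n20 A NATAA  # repack only\n")
        spec = DesignSpec.from_resfile(rf)
        assert spec.default_mode == "NATRO"
        assert spec.mode_of("A", 10) == "ALLAA"
        assert spec.mode_of("A", 20) == "NATAA"
        assert spec.mode_of("A", 99) == "NATRO"

    def test_absent_residue_rejected(self, small_pocket):
        model, _, _ = small_pocket
        spec = DesignSpec(modes={("A", 999): "ALLAA"})
        with pytest.raises(LookupError):
            pack(model, spec)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_step(0.0, -1.0, 1.0, rng) for _ in range(100))

    def test_uphill_acceptance_matches_closed_form(self):
        rng = np.random.default_rng(12345)
        n = 100_000
        accepted = sum(metropolis_step(0.0, 1.0, 1.0, rng) for _ in range(n))
        assert accepted / n == pytest.approx(math.exp(-1.0), abs=0.01)

    def test_low_temperature_limit_is_greedy(self):
        rng = np.random.default_rng(0)
        accepted = sum(metropolis_step(0.0, 1.0, 1e-8, rng) for _ in range(10_000))
        assert accepted == 0

    def test_kt_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            metropolis_step(0.0, 1.0, 0.0, rng)


class TestPack:
    def test_natro_only_is_identity(self, small_pocket):
        model, _, _ = small_pocket
        out, log = pack(model, DesignSpec(default_mode="NATRO"))
        assert log == []
        assert np.allclose(out.coords, model.coords)

    def test_annealing_finds_exhaustive_optimum(self, design_pocket):
        model, _, gt = design_pocket
        site = gt["designable"]["residue"]
        spec = DesignSpec(
            modes={(site[0], site[1]): "ALLAA"},
            allowed={(site[0], site[1]): ["SER", "THR", "ALA"]},
        )
        best_ex, log_ex = pack(model, spec, exhaustive=True)
        best_an, log_an = pack(model, spec, AnnealingSchedule(seed=11, n_steps=150))
        e_ex = log_ex[0]["best_energy"]
        e_an = min(entry["best"] for entry in log_an)
        assert e_an == pytest.approx(e_ex, abs=1e-9)

    def test_deterministic_given_seed(self, design_pocket):
        model, _, gt = design_pocket
        site = gt["designable"]["residue"]
        spec = DesignSpec(modes={(site[0], site[1]): "ALLAA"})
        sched = AnnealingSchedule(seed=3, n_steps=30)
        out1, log1 = pack(model, spec, sched)
        out2, log2 = pack(model, spec, sched)
        assert np.array_equal(out1.coords, out2.coords)
        assert log1 == log2

    def test_gain_of_contact_design(self, design_pocket):
        """On the planted fixture, adding a polar bond is optimal by
        construction, and design finds it: the contact count increases."""
        model, lig, gt = design_pocket
        site = gt["designable"]["residue"]
        n_before = len(polar_contacts(model, extract_ligand(model, "X9X")))
        spec = DesignSpec(modes={(site[0], site[1]): "ALLAA"})
        best, _ = pack(model, spec, AnnealingSchedule(seed=7))
        n_after = len(polar_contacts(best, extract_ligand(best, "X9X")))
        assert n_after > n_before

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(kT_start=0.1, kT_end=1.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(n_steps=0)


class TestMutateResidue:
    def test_backbone_fixed_side_chain_replaced(self, small_pocket):
        model, _, _ = small_pocket
        key = ("A", 10)  # planted HIS
        out = mutate_residue(model, key, "TRP", (180.0, 90.0))
        res = {k: v for k, v in out.residues().items() if k[1] == 10}
        assert list(res) == [("A", 10, "TRP")]
        old_bb = {
            a.name: a.position
            for a in model.atoms
            if a.residue_seq == 10 and a.name in ("N", "CA", "C", "O")
        }
        new_bb = {
            a.name: a.position
            for a in out.atoms
            if a.residue_seq == 10 and a.name in ("N", "CA", "C", "O")
        }
        for name in old_bb:
            assert np.allclose(old_bb[name], new_bb[name])

    def test_unknown_target_or_residue(self, small_pocket):
        model, _, _ = small_pocket
        with pytest.raises(KeyError):
            mutate_residue(model, ("A", 10), "XYZ", ())
        with pytest.raises(LookupError):
            mutate_residue(model, ("A", 999), "ALA", ())


class TestMinimize:
    def test_energy_never_increases(self, small_pocket, params):
        model, _, _ = small_pocket
        e0 = score(model, params).total
        out = minimize(model, params=params, max_sweeps=2)
        assert score(out, params).total <= e0 + 1e-9

    def test_local_minimum_is_fixed_point(self, small_pocket, params):
        model, _, _ = small_pocket
        once = minimize(model, params=params, max_sweeps=4)
        again = minimize(once, params=params, max_sweeps=1, coarse_deg=30.0)
        assert score(again, params).total == pytest.approx(
            score(once, params).total, abs=1e-3
        )

    def test_single_torsion_reaches_grid_optimum(self, small_pocket, params):
        # one movable chi: cyclic descent must match an exhaustive fine scan
        model, _, _ = small_pocket
        torsions = sidechain_torsions(model)
        quad, moving = torsions[0]
        out = minimize(model, [(quad, moving)], params=params, coarse_deg=5.0)
        e_got = score(out, params).total

        from sbpdesign.geometry import rotation_about_axis

        best = np.inf
        xyz0 = model.coords
        origin, axis = xyz0[quad[1]], xyz0[quad[2]] - xyz0[quad[1]]
        for deg in np.arange(-180.0, 180.0, 0.5):
            trial = model.copy()
            R = rotation_about_axis(axis, np.deg2rad(deg))
            txyz = trial.coords
            for mi in moving:
                txyz[mi] = origin + R @ (txyz[mi] - origin)
            trial.set_coords(txyz)
            best = min(best, score(trial, params).total)
        assert e_got <= best + 0.05  # within the fine-grid resolution


class TestRelax:
    def test_zero_cycles_is_identity(self, small_pocket, params):
        model, _, _ = small_pocket
        out = relax(model, n_cycles=0, params=params)
        assert np.allclose(out.coords, model.coords)

    def test_clash_resolved_and_energy_drops(self, params):
        model, lig, _ = make_pocket(
            FixtureSpec(seed=3, contacts=[("HIS", 2.9)], spectators=[], clash=("LEU", 1.6))
        )
        e0 = score(model, params).total
        out = relax(model, n_cycles=1, params=params, seed=5)
        e1 = score(out, params).total
        assert e1 < e0
        lig_xyz = np.array([a.position for a in out.atoms if a.is_hetero])
        prot_xyz = np.array([a.position for a in out.atoms if not a.is_hetero])
        min_d = np.min(
            np.linalg.norm(prot_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
        )
        assert min_d > 2.4


class TestRepeatOptimize:
    def test_output_energy_not_above_input(self, small_pocket, params):
        model, _, _ = small_pocket
        out = repeat_optimize(model, kT=1.0, n=2, seed=1, params=params)
        assert score(out, params).total <= score(model, params).total + 1e-9

    def test_n_one_equals_single_sweep(self, small_pocket, params):
        model, _, _ = small_pocket
        multi = repeat_optimize(model, kT=1.0, n=1, seed=9, params=params)
        sched = AnnealingSchedule(kT_start=1.0, kT_end=1.0, seed=9)
        single, _ = pack(model, DesignSpec(default_mode="NATAA"), sched, params=params)
        e_single = min(
            score(single, params).total, score(model, params).total
        )
        assert score(multi, params).total == pytest.approx(e_single, abs=1e-9)

    def test_seed_sweep_varies_on_frustrated_fixture(self, params, default_pocket):
        # seven repackable residues give a rotamer space far larger than one
        # kT=1 sweep can cover, so different seeds end in different optima
        model, _, _ = default_pocket
        energies = {
            round(score(repeat_optimize(model, kT=1.0, n=1, seed=s, params=params), params).total, 6)
            for s in range(5)
        }
        assert len(energies) > 1
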