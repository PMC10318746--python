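"""PDB reading/writing and monomer/ligand extraction."""

import numpy as np
import pytest

from sbpdesign.structure_io import (
    Atom,
    EmptyStructureError,
    StructureModel,
    extract_ligand,
    extract_monomer,
    read_pdb,
    remove_ligand,
    write_pdb,
)
from sbpdesign.synthetic_data import FixtureSpec, make_dimer


FIVE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.836  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.247   4.682  -4.939  1.00  0.00           C
END
"""


def test_read_hand_written_fixture(tmp_path):
    p = tmp_path / "five.pdb"
    p.write_text(FIVE_ATOM_PDB)
    model = read_pdb(p)
    assert len(model) == 5
    assert model.chain_ids == ["A"]
    assert len(model.residues()) == 1
    assert [a.name for a in model.atoms] == ["N", "CA", "C", "O", "CB"]
    assert np.allclose(model.atoms[0].position, [11.104, 6.134, -6.504])


def test_read_missing_and_empty_files(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_pdb(tmp_path / "nope.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(EmptyStructureError):
        read_pdb(empty)


def test_write_read_round_trip(tmp_path, default_pocket):
    model, _, _ = default_pocket
    p = tmp_path / "pocket.pdb"
    write_pdb(model, p)
    back = read_pdb(p)
    assert len(back) == len(model)
    assert [a.name for a in back.atoms] == [a.name for a in model.atoms]
    assert [a.residue_name for a in back.atoms] == [a.residue_name for a in model.atoms]
    assert [a.record_kind for a in back.atoms] == [a.record_kind for a in model.atoms]
    assert np.allclose(back.coords, model.coords, atol=1e-3)
    # second round trip is textually identical: format precision reached fixpoint
    p2 = tmp_path / "pocket2.pdb"
    write_pdb(back, p2)
    assert p.read_text() == p2.read_text()


def test_write_empty_model_errors(tmp_path):
    with pytest.raises(EmptyStructureError):
        write_pdb(StructureModel([]), tmp_path / "x.pdb")


def test_waters_dropped_by_default(tmp_path):
    p = tmp_path / "wet.pdb"
    p.write_text(
        FIVE_ATOM_PDB.replace(
            "END",
            "HETATM    6  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O\nEND",
        )
    )
    assert len(read_pdb(p)) == 5
    assert len(read_pdb(p, keep_waters=True)) == 6


class TestExtractMonomer:
    def test_homodimer_halves(self):
        dimer = make_dimer(FixtureSpec(seed=1))
        mono = extract_monomer(dimer, "A")
        assert len(mono) * 2 == len(dimer)
        assert {a.chain_id for a in mono.atoms} == {"A"}

    def test_idempotent(self):
        dimer = make_dimer(FixtureSpec(seed=1))
        once = extract_monomer(dimer, "A")
        twice = extract_monomer(once, "A")
        assert np.allclose(once.coords, twice.coords)
        assert [a.name for a in once.atoms] == [a.name for a in twice.atoms]

    def test_matches_brute_force_chain_filter(self, rng):
        # random 3-chain synthetic model: extraction equals a plain filter
        atoms = []
        serial = 1
        for chain in "ABC":
            for seq in range(1, 4):
                for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                    atoms.append(
                        Atom(
                            serial=serial,
                            name=name,
                            element=el,
                            position=rng.normal(scale=20.0, size=3),
                            residue_name="GLY",
                            chain_id=chain,
                            residue_seq=seq,
                        )
                    )
                    serial += 1
        model = StructureModel(atoms)
        got = extract_monomer(model, "A")
        expected = [a for a in model.atoms if a.chain_id == "A"]
        assert len(got) == len(expected)
        assert np.allclose(got.coords, np.array([a.position for a in expected]))

    def test_absent_chain(self):
        dimer = make_dimer(FixtureSpec(seed=1))
        with pytest.raises(LookupError):
            extract_monomer(dimer, "Z")

    def test_orphan_hetatm_assigned_to_nearest_chain(self, default_pocket):
        model, _, _ = default_pocket
        reassigned = model.copy()
        for a in reassigned.atoms:
            if a.is_hetero:
                a.chain_id = "X"  # chain id matching no protein chain
        mono = extract_monomer(reassigned, "A")
        assert sum(a.is_hetero for a in mono.atoms) == sum(
            a.is_hetero for a in model.atoms
        )


class TestExtractLigand:
    def test_planted_ligand_atom_count(self, default_pocket):
        model, ligand, _ = default_pocket
        got = extract_ligand(model, "X9X")
        assert len(got.atoms) == len(ligand.atoms)
        assert all(a.residue_name == "X9X" for a in got.atoms)

    def test_count_matches_independent_record_scan(self, tmp_path, default_pocket):
        model, _, _ = default_pocket
        p = tmp_path / "m.pdb"
        write_pdb(model, p)
        n_records = sum(
            1
            for line in p.read_text().splitlines()
            if line.startswith("HETATM") and line[17:20].strip() == "X9X"
        )
        assert len(extract_ligand(model, "X9X").atoms) == n_records

    def test_unknown_code_errors(self, default_pocket):
        model, _, _ = default_pocket
        with pytest.raises(LookupError):
            extract_ligand(model, "ZZZ")

    def test_multiple_copies_need_chain(self):
        dimer = make_dimer(FixtureSpec(seed=1))
        with pytest.raises(LookupError):
            extract_ligand(dimer, "X9X")
        lig = extract_ligand(dimer, "X9X", chain="B")
        assert all(a.chain_id == "B" for a in lig.atoms)

    def test_extraction_plus_removal_partitions_atoms(self, default_pocket):
        model, _, _ = default_pocket
        lig = extract_ligand(model, "X9X")
        rest = remove_ligand(model, "X9X")
        assert len(lig.atoms) + len(rest) == len(model)
        assert not any(a.residue_name == "X9X" for a in rest.atoms)
        # source model untouched
        assert any(a.residue_name == "X9X" for a in model.atoms)
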