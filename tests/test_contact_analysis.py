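"""Pocket selection and polar-contact detection against planted ground truth."""

import numpy as np
import pytest

from sbpdesign.contact_analysis import (
    ContactCriteria,
    PolarContact,
    contact_report,
    polar_contacts,
    residues_within,
)
from sbpdesign.synthetic_data import FixtureSpec, make_pocket


def brute_force_residues_within(model, ligand, cutoff):
    """Independent O(N*M) oracle for pocket selection."""
    lig = np.array([a.position for a in ligand.atoms if a.element != "H"])
    hits = set()
    for a in model.atoms:
        if a.is_hetero or a.element == "H":
            continue
        d = np.min(np.linalg.norm(lig - a.position, axis=1))
        if d <= cutoff:
            hits.add((a.chain_id, a.residue_seq, a.residue_name))
    return sorted(hits, key=lambda k: (k[0], k[1]))


class TestResiduesWithin:
    def test_planted_distances_select_exactly_two(self):
        # residues at min distances 3.0 / 3.9 / 4.1: the 4.0 cutoff keeps two
        model, lig, _ = make_pocket(
            FixtureSpec(
                seed=4,
                contacts=[("SER", 3.0)],
                spectators=[("VAL", 3.9), ("PHE", 4.1)],
            )
        )
        got = residues_within(model, lig, 4.0)
        assert [k[1] for k in got] == [10, 20]

    def test_zero_cutoff_empty(self, default_pocket):
        model, lig, _ = default_pocket
        assert residues_within(model, lig, 0.0) == []

    def test_matches_brute_force_oracle(self, default_pocket):
        model, lig, _ = default_pocket
        for cutoff in (2.0, 3.0, 3.5, 4.0, 6.0, 10.0):
            assert residues_within(model, lig, cutoff) == brute_force_residues_within(
                model, lig, cutoff
            )

    def test_monotone_in_cutoff(self, default_pocket):
        model, lig, _ = default_pocket
        cutoffs = [1.0, 2.5, 3.0, 3.5, 4.0, 5.0, 8.0]
        sets = [set(residues_within(model, lig, c)) for c in cutoffs]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_empty_ligand_rejected(self, default_pocket):
        model, lig, _ = default_pocket
        bare = lig.copy()
        bare.atoms = []
        with pytest.raises(ValueError):
            residues_within(model, bare, 4.0)


class TestPolarContacts:
    def test_planted_pair_at_good_distance_detected(self):
        model, lig, gt = make_pocket(
            FixtureSpec(seed=5, contacts=[("SER", 2.9)], spectators=[])
        )
        found = polar_contacts(model, lig)
        assert len(found) == 1
        assert found[0].distance == pytest.approx(2.9, abs=1e-6)
        assert found[0].kind == "protein-ligand"

    def test_same_pair_beyond_window_not_detected(self):
        # take the 2.9 A fixture and push the residue out to ~5 A
        model, lig, gt = make_pocket(
            FixtureSpec(seed=5, contacts=[("SER", 2.9)], spectators=[])
        )
        lig_center = np.mean([a.position for a in lig.atoms], axis=0)
        far = model.copy()
        for a in far.atoms:
            if not a.is_hetero:
                away = a.position - lig_center
                a.position = a.position + 2.1 * away / np.linalg.norm(away)
        assert polar_contacts(far, lig) == []

    def test_ground_truth_counts_recovered(self, default_pocket):
        model, lig, gt = default_pocket
        found = polar_contacts(model, lig)
        assert len(found) == gt["n_contacts"]
        assert sorted({c.residue for c in found}, key=lambda k: k[1]) == sorted(
            set(gt["contact_residues"]), key=lambda k: k[1]
        )

    def test_contacts_subset_of_pocket_at_polar_window(self, default_pocket):
        model, lig, _ = default_pocket
        criteria = ContactCriteria()
        pocket = set(residues_within(model, lig, criteria.polar_distance_max))
        assert {c.residue for c in polar_contacts(model, lig, criteria)} <= pocket

    def test_no_pair_double_counted(self, default_pocket):
        model, lig, _ = default_pocket
        found = polar_contacts(model, lig)
        pairs = {(id(c.atom_a), id(c.atom_b)) for c in found}
        assert len(pairs) == len(found)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ContactCriteria(polar_distance_min=3.5, polar_distance_max=2.4)


class TestContactReport:
    def test_identical_states_zero_delta(self, default_pocket):
        model, lig, _ = default_pocket
        found = polar_contacts(model, lig)
        df = contact_report({"before": found, "after": found})
        assert (df["before"] == df["after"]).all()

    def test_planted_gain_shows_plus_one(self):
        key = ("A", 40, "SER")
        before = {key: 1}
        after = {key: 2}
        df = contact_report({"before": before, "after": after})
        assert df.loc["40 SER", "after"] - df.loc["40 SER", "before"] == 1

    def test_totals_row_equals_independent_sum(self, default_pocket):
        model, lig, _ = default_pocket
        found = polar_contacts(model, lig)
        df = contact_report({"contacts": found})
        per_residue = df.drop(index="TOTAL")["contacts"]
        assert df.loc["TOTAL", "contacts"] == per_residue.sum() == len(found)

    def test_zero_contact_pocket_residues_listed(self, default_pocket):
        model, lig, gt = default_pocket
        found = polar_contacts(model, lig)
        df = contact_report({"contacts": found}, pocket_residues=gt["pocket_residues"])
        spectators = [
            k for k in gt["pocket_residues"] if k not in set(gt["contact_residues"])
        ]
        for k in spectators:
            assert df.loc[f"{k[1]} {k[2]}", "contacts"] == 0
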