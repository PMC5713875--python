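"""Contact parsing, top-L selection, FADE restraints, precision, interfaces."""

import numpy as np
import pytest

from helixmr.contacts import (
    ContactPrediction,
    FadeParams,
    contact_precision,
    contacts_to_restraints,
    interface_contacts,
    parse_contacts,
    select_top_L,
    write_contacts,
)
from helixmr.errors import PdbFormatError, ValidationError
from helixmr.structure import Atom, Residue, StructureModel


def residue_at(seq_id, cb_xyz, res_name="ALA"):
    cb = np.asarray(cb_xyz, float)
    atoms = [Atom("N", "N", cb + [0.0, 1.2, 0.8]),
             Atom("CA", "C", cb + [0.0, 0.0, 1.5]),
             Atom("C", "C", cb + [0.8, -0.9, 1.2]),
             Atom("O", "O", cb + [1.2, -1.8, 1.6])]
    if res_name != "GLY":
        atoms.append(Atom("CB", "C", cb))
    return Residue(seq_id, res_name, atoms)


def chain_model(cb_positions, model_id="m", res_names=None, start_seq=1):
    residues = []
    for k, pos in enumerate(cb_positions):
        name = res_names[k] if res_names else "ALA"
        residues.append(residue_at(start_seq + k, pos, name))
    return StructureModel(model_id, {"A": residues})


class TestParsing:
    def test_casp_rr_round_trip(self, tmp_path):
        contacts = [ContactPrediction(1, 10, 0.9), ContactPrediction(2, 30, 0.5),
                    ContactPrediction(7, 40, 0.75)]
        p = tmp_path / "c.rr"
        write_contacts(contacts, p, "casp_rr")
        back = parse_contacts(p, "casp_rr")
        assert back == contacts

    def test_three_column_dialect(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("1 10 0.9\n2 30 0.5\n3 40 0.1\n")
        assert len(parse_contacts(p, "3col")) == 3

    def test_duplicates_collapse_to_max_confidence(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("5 20 0.9\n20 5 0.7\n")
        (c,) = parse_contacts(p, "3col")
        assert (c.res_i, c.res_j, c.confidence) == (5, 20, 0.9)

    def test_rr_headers_and_sequence_skipped(self, tmp_path):
        p = tmp_path / "c.rr"
        p.write_text("PFRMAT RR\nTARGET T0001\nMAHHHHHH\n1 10 0 8 0.9\nEND\n")
        assert len(parse_contacts(p, "casp_rr")) == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("1 10 0.9\n2 oops 0.5\n")
        with pytest.raises(PdbFormatError, match="line 2"):
            parse_contacts(p, "3col")

    def test_minimum_separation_filter(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("1 3 0.9\n1 6 0.8\n1 5 0.7\n")
        got = parse_contacts(p, "3col", min_separation=5)
        assert [(c.res_i, c.res_j) for c in got] == [(1, 6)]


class TestTopL:
    def test_selects_highest_confidence(self):
        contacts = [ContactPrediction(1, 10 + k, k / 100.0) for k in range(100)]
        top = select_top_L(contacts, 50)
        assert len(top) == 50
        assert min(c.confidence for c in top) >= 0.50

    def test_zero_l_empty(self):
        assert select_top_L([ContactPrediction(1, 10, 0.9)], 0) == []

    def test_equal_confidence_ties_lexicographic(self):
        contacts = [ContactPrediction(i, j, 0.5)
                    for i in (3, 1, 2) for j in (20, 15)]
        top = select_top_L(contacts, 3)
        assert [(c.res_i, c.res_j) for c in top] == [(1, 15), (1, 20), (2, 15)]

    def test_nested_selection_precision_non_increasing(self):
        """When confidence ranks correctness, precision can only fall as L
        grows."""
        sep = 30.0
        positions = [np.array([3.8 * k, 0.0, 0.0]) for k in range(20)]
        structure = chain_model(positions)
        contacts = []
        # high-confidence true pairs (close in space), low-confidence false
        for k in range(5):
            contacts.append(ContactPrediction(k + 1, k + 2 + 5, 0.9 - 0.01 * k))
        for k in range(5):
            contacts.append(ContactPrediction(k + 1, k + 15, 0.2 - 0.01 * k))
        prev = 1.0
        for L in (2, 4, 6, 8, 10):
            p = contact_precision(select_top_L(contacts, L), structure)
            assert p <= prev + 1e-12
            prev = p


class TestRestraints:
    def test_one_restraint_per_contact_in_order(self):
        contacts = [ContactPrediction(1, 10, 0.9), ContactPrediction(2, 12, 0.8)]
        rs = contacts_to_restraints(contacts, "A" * 20)
        assert len(rs) == 2
        lines = rs.to_lines()
        assert lines[1].startswith("AtomPair CB 1 CB 10 FADE")
        assert lines[2].startswith("AtomPair CB 2 CB 12 FADE")

    def test_glycine_uses_ca(self):
        seq = "GAAAAAAAAAAAAAAAAAAA"  # GLY at position 1
        (r,) = contacts_to_restraints([ContactPrediction(1, 10, 0.9)], seq).restraints
        assert (r[0], r[2]) == ("CA", "CB")

    def test_fade_parameters_serialised(self, tmp_path):
        params = FadeParams(lower=-10, upper=19, fade_zone=10, well_depth=-15.0)
        rs = contacts_to_restraints([ContactPrediction(1, 10, 0.9)], "A" * 10, params)
        line = rs.to_lines()[1]
        assert line.endswith("FADE -10 19 10 -15.00")
        p = tmp_path / "r.cst"
        rs.write(p)
        assert p.read_text().count("AtomPair") == 1

    def test_empty_contact_list_header_only(self):
        rs = contacts_to_restraints([], "A" * 10)
        assert len(rs) == 0
        assert rs.to_lines() == ["# 0 atom-pair FADE restraints"]

    def test_residue_outside_sequence_rejected(self):
        with pytest.raises(ValidationError):
            contacts_to_restraints([ContactPrediction(1, 30, 0.9)], "A" * 10)


class TestPrecision:
    def test_engineered_fraction_exact(self):
        """Pairs built at known CB distances give exactly the engineered
        true fraction."""
        dists = [4.0, 5.0, 6.0, 7.0, 7.9, 8.0, 9.0, 10.0, 12.0, 20.0]
        structure = chain_model([np.zeros(3)] + [np.array([d, 0.0, 0.0]) for d in dists])
        # pairs (1,6)..(1,11) have CB distances 7.9, 8.0, 9.0, 10.0, 12.0, 20.0
        contacts = [ContactPrediction(1, j, 0.5) for j in range(6, 12)]
        assert contact_precision(contacts, structure) == pytest.approx(2 / 6)

    def test_all_close_pairs_full_precision(self):
        positions = [np.array([k * 1.0, 0.0, 0.0]) for k in range(10)]
        structure = chain_model(positions)
        contacts = [ContactPrediction(1, 8, 0.9), ContactPrediction(2, 9, 0.8)]
        assert contact_precision(contacts, structure) == 1.0

    def test_boundary_pair_at_cutoff_counts_true(self):
        structure = chain_model([np.zeros(3), np.array([8.0, 0.0, 0.0])],
                                start_seq=1)
        structure.chains["A"][1].seq_id = 10
        assert contact_precision([ContactPrediction(1, 10, 0.9)], structure) == 1.0

    def test_missing_residue_counts_false(self):
        structure = chain_model([np.zeros(3), np.array([4.0, 0.0, 0.0])])
        contacts = [ContactPrediction(1, 2 + 4, 0.9)]  # residue 6 absent
        assert contact_precision(contacts, structure) == 0.0


class TestInterface:
    def test_superposed_chains_degenerate_to_intra(self):
        # compact trace: pairs 6 apart sit at 7.8 A, within the cutoff
        positions = [np.array([1.3 * k, 0.0, 0.0]) for k in range(12)]
        a = chain_model(positions, "a")
        b = chain_model(positions, "b")
        contacts = [ContactPrediction(1, 7, 0.5), ContactPrediction(2, 8, 0.5)]
        intra = sum(contact_precision([c], a) for c in contacts)
        assert intra == 2
        count, _ = interface_contacts(contacts, a, b)
        assert count == intra

    def test_far_apart_chains_zero(self):
        positions = [np.array([3.8 * k, 0.0, 0.0]) for k in range(12)]
        a = chain_model(positions, "a")
        b = chain_model([p + np.array([0.0, 100.0, 0.0]) for p in positions], "b")
        count, mean_conf = interface_contacts(
            [ContactPrediction(1, 7, 0.5)], a, b)
        assert count == 0 and mean_conf == 0.0

    def test_engineered_cross_interface_pairs(self):
        """5 engineered cross-chain pairs are found with their mean score."""
        n = 30
        far = np.array([0.0, 500.0, 0.0])
        pa = [np.array([20.0 * k, 0.0, 0.0]) for k in range(n)]
        pb = [p + far for p in pa]
        confs = [0.9, 0.8, 0.7, 0.6, 0.5]
        contacts = []
        for k, conf in enumerate(confs):
            i, j = 2 * k + 1, 2 * k + 8
            pb[j - 1] = pa[i - 1] + np.array([5.0, 0.0, 0.0])  # j of B near i of A
            contacts.append(ContactPrediction(i, j, conf))
        contacts.append(ContactPrediction(21, 30, 0.99))  # not engineered: stays far
        a = chain_model(pa, "a")
        b = chain_model(pb, "b")
        count, mean_conf = interface_contacts(contacts, a, b)
        assert count == 5
        assert mean_conf == pytest.approx(np.mean(confs))
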