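"""Variance truncation, subclustering, side-chain editing, ensemble sweep."""

import re
from math import ceil

import numpy as np
import pytest

from helixmr.clustering import DecoyCluster, DecoySet
from helixmr.decoys import residue_labels
from helixmr.ensembler import (
    VarianceProfile,
    apply_sidechain_mode,
    per_residue_variance,
    subcluster,
    truncate,
    truncate_model,
)
from helixmr.errors import ValidationError
from helixmr.helices import build_ideal_helix
from helixmr.scoring import kabsch
from helixmr.structure import Atom, Residue, StructureModel, ca_coords

NAME_RE = re.compile(r"^c\d+_t\d+_r[123]_(polyAla|reliable|allatom)$")


def two_identical(base):
    return DecoySet([base.copy(model_id="a"), base.copy(model_id="b")])


def trivial_cluster(dset, cutoff=1.0):
    ids = [d.model_id for d in dset.decoys]
    return DecoyCluster(1, ids[0], ids, cutoff,
                        rmsd_to_centroid={i: 0.0 for i in ids})


class TestVariance:
    def test_identical_members_zero_variance(self):
        dset = two_identical(build_ideal_helix(10))
        prof = per_residue_variance(trivial_cluster(dset), dset)
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in prof.per_residue)

    def test_flexible_regions_have_higher_variance(self, capped_top_cluster,
                                                   decoy_set, study_spec):
        prof = per_residue_variance(capped_top_cluster, decoy_set)
        labels = residue_labels(study_spec)
        var = np.array([v for _, v in prof.per_residue])
        helix = var[[i for i, l in enumerate(labels) if l == "helix"]]
        flex = var[[i for i, l in enumerate(labels) if l != "helix"]]
        assert flex.mean() > helix.mean()

    def test_variance_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        base = build_ideal_helix(12)
        noisy = []
        for k in range(4):
            c = base.copy(model_id=f"m{k}")
            for res in c.residues():
                for a in res.atoms:
                    a.position = a.position + rng.normal(0, 0.3, 3)
            noisy.append(c)
        dset = DecoySet(noisy)
        prof1 = per_residue_variance(trivial_cluster(dset), dset)
        rot = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        moved = DecoySet([d.transformed(rot, np.array([3.0, 4.0, 5.0]),
                                        model_id=d.model_id) for d in noisy])
        prof2 = per_residue_variance(trivial_cluster(moved), moved)
        for (_, v1), (_, v2) in zip(prof1.per_residue, prof2.per_residue):
            assert v1 == pytest.approx(v2, abs=1e-9)

    def test_missing_ca_rejected(self):
        dset = two_identical(build_ideal_helix(10))
        res = dset.decoys[1].chains["A"][4]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(ValidationError):
            per_residue_variance(trivial_cluster(dset), dset)


class TestTruncate:
    def test_kept_counts_in_five_percent_steps(self):
        prof = VarianceProfile(tuple((i, float(i)) for i in range(1, 101)))
        levels = truncate(prof, 20)
        assert [len(l.kept_residues) for l in levels] == list(range(5, 101, 5))
        assert levels[-1].fraction == 1.0

    def test_single_bin_keeps_everything(self):
        prof = VarianceProfile(tuple((i, float(i)) for i in range(1, 11)))
        (lvl,) = truncate(prof, 1)
        assert lvl.kept_residues == frozenset(range(1, 11))

    def test_levels_nest_and_fractions_increase(self):
        prof = VarianceProfile(tuple((i, float((i * 37) % 11)) for i in range(1, 93)))
        levels = truncate(prof, 20)
        for a, b in zip(levels, levels[1:]):
            assert a.kept_residues <= b.kept_residues
            assert a.fraction < b.fraction

    def test_variance_ties_keep_lower_seq_id_first(self):
        prof = VarianceProfile(((5, 1.0), (1, 1.0), (3, 1.0), (2, 0.5)))
        levels = truncate(prof, 4)
        assert levels[0].kept_residues == frozenset({2})
        assert levels[1].kept_residues == frozenset({1, 2})
        assert levels[2].kept_residues == frozenset({1, 2, 3})


class TestSubcluster:
    def test_identical_members_all_returned(self):
        base = build_ideal_helix(10)
        members = [base.copy(model_id=f"m{k}") for k in range(8)]
        assert len(subcluster(members, 1.0)) == 8

    def test_far_outlier_excluded(self):
        from helixmr.helices import build_bent_helix

        base = build_ideal_helix(10)
        members = [base.copy(model_id=f"m{k}") for k in range(4)]
        far = build_bent_helix(10, 60.0).copy(model_id="far")  # ~1.5 A away
        out = subcluster(members + [far], 1.0)
        assert {m.model_id for m in out} == {f"m{k}" for k in range(4)}

    def test_cap_of_thirty(self):
        base = build_ideal_helix(10)
        members = [base.copy(model_id=f"m{k}") for k in range(40)]
        assert len(subcluster(members, 1.0)) == 30


class TestSidechainModes:
    @staticmethod
    def mixed_chain():
        lys_atoms = [Atom(n, n[0], [i * 0.5, 0.0, 0.0]) for i, n in
                     enumerate(["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"])]
        ala_atoms = [Atom(n, n[0], [i * 0.5, 1.0, 0.0]) for i, n in
                     enumerate(["N", "CA", "C", "O", "CB"])]
        return StructureModel("mix", {"A": [
            Residue(1, "ALA", [a.copy() for a in ala_atoms]),
            Residue(2, "LYS", [a.copy() for a in lys_atoms]),
        ]})

    def test_allatom_is_identity_on_atom_counts(self):
        m = self.mixed_chain()
        out = apply_sidechain_mode(m, "allatom")
        assert out.n_atoms == m.n_atoms

    def test_polyalanine_strips_lysine_to_five_atoms(self):
        out = apply_sidechain_mode(self.mixed_chain(), "polyalanine")
        lys = out.chains["A"][1]
        assert [a.name for a in lys.atoms] == ["N", "CA", "C", "O", "CB"]

    def test_reliable_keeps_low_rotamer_side_chains_only(self):
        out = apply_sidechain_mode(self.mixed_chain(), "reliable")
        ala, lys = out.chains["A"]
        assert len(ala.atoms) == 5  # unchanged
        assert [a.name for a in lys.atoms] == ["N", "CA", "C", "O", "CB"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            apply_sidechain_mode(self.mixed_chain(), "backbone")


class TestEnsembleSweep:
    def test_names_match_convention(self, ensembles):
        for e in ensembles:
            assert NAME_RE.match(e.name), e.name

    def test_factorial_bound(self, ensembles):
        assert 0 < len(ensembles) <= 180  # 20 bins x 3 radii x 3 modes

    def test_members_share_kept_residues(self, ensembles):
        for e in ensembles:
            for m in e.members:
                assert {r.seq_id for r in m.residues()} == set(e.kept_residues)

    def test_member_counts_capped(self, ensembles):
        assert all(1 <= e.size <= 30 for e in ensembles)

    def test_subcluster_diameter_bound(self, ensembles):
        """Max pairwise member RMSD within an ensemble is <= 2x the radius."""
        for e in ensembles:
            if e.sidechain_mode != "polyalanine" or e.size < 2:
                continue
            xyz = [ca_coords(m) for m in e.members]
            for i in range(len(xyz)):
                for j in range(i + 1, len(xyz)):
                    assert kabsch(xyz[i], xyz[j]).rmsd <= 2.0 * e.subcluster_radius + 1e-9

    def test_no_duplicate_member_sets_within_level(self, ensembles):
        seen = set()
        for e in ensembles:
            if e.sidechain_mode != "polyalanine":
                continue
            key = (e.truncation_level, frozenset(m.model_id for m in e.members))
            assert key not in seen
            seen.add(key)

    def test_rmsd_to_truth_non_increasing_with_truncation(self, ensembles, ground_truth):
        truth = {r.seq_id: r.ca.position for r in ground_truth.chains["A"]}
        means = {}
        for lvl in range(5, 21):
            vals = []
            for e in ensembles:
                if e.truncation_level != lvl or e.sidechain_mode != "polyalanine":
                    continue
                seqs = sorted(e.kept_residues)
                ref = np.array([truth[s] for s in seqs])
                for m in e.members:
                    by_seq = {r.seq_id: r.ca.position for r in m.residues()}
                    vals.append(kabsch(np.array([by_seq[s] for s in seqs]), ref).rmsd)
            means[lvl] = np.mean(vals)
        for lvl in range(5, 20):
            assert means[lvl] <= means[lvl + 1] + 0.02


def test_truncate_model_preserves_numbering(helix20):
    kept = frozenset({1, 2, 3, 10, 11, 12})
    t = truncate_model(helix20, kept)
    assert [r.seq_id for r in t.residues()] == [1, 2, 3, 10, 11, 12]
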