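"""Allele seeding, unit propagation, conflicts, imputation, accuracy."""

import numpy as np
import pytest

import pedimpute as pi
from pedimpute.demo import COLORS, FAMILY
from pedimpute.impute import ImputationResult, LocusStatus, _LocusSolver, impute_locus
from pedimpute.pedigree import GenotypeMatrix, MarkerMap

from conftest import enumerate_satisfying, random_locus_instance


def run_solver(members, family="F", marker=0):
    s = _LocusSolver(family, marker)
    s.seed(members)
    s.propagate(members)
    return s


class TestSeedingAndPropagation:
    def test_homozygote_seeds_both_labels(self, demo_data):
        asg, conflicts = pi.seed_from_homozygotes(
            0, FAMILY, 0, demo_data["labeling"], demo_data["seq_genotypes"],
            demo_data["pedigree"],
        )
        assert conflicts == []
        assert asg.assigned[COLORS["pink"]] == 1
        assert asg.assigned[COLORS["dark_blue"]] == 1
        assert COLORS["light_blue"] in asg.unresolved

    def test_propagation_resolves_het_partners(self, demo_data):
        seeded, _ = pi.seed_from_homozygotes(
            0, FAMILY, 0, demo_data["labeling"], demo_data["seq_genotypes"],
            demo_data["pedigree"],
        )
        asg, conflicts = pi.propagate_to_fixed_point(
            seeded, 0, FAMILY, 0, demo_data["labeling"], demo_data["seq_genotypes"],
            demo_data["pedigree"],
        )
        assert conflicts == []
        # 974's homozygote anchors pink=1; 940 resolves light blue, 939 green,
        # and 956's heterozygote then resolves yellow from green
        assert asg.assigned[COLORS["light_blue"]] == 2
        assert asg.assigned[COLORS["green"]] == 2
        assert asg.assigned[COLORS["yellow"]] == 1
        assert COLORS["light_green"] in asg.unresolved

    def test_two_homozygotes_sharing_a_label_conflict(self):
        L = lambda f: pi.Label("F", f, 1)
        members = [
            ("a", (L("pink"), L("x")), (1, 1)),
            ("b", (L("pink"), L("y")), (2, 2)),
        ]
        s = run_solver(members)
        assert len(s.conflicts) == 1
        c = s.conflicts[0]
        assert c.label == L("pink")
        assert {c.allele_a, c.allele_b} == {1, 2}
        assert {c.witness_a, c.witness_b} == {"a", "b"}

    def test_unreachable_het_component_stays_unassigned(self):
        L = lambda f: pi.Label("F", f, 1)
        members = [
            ("hom", (L("a"), L("a")), (1, 1)),
            ("h1", (L("x"), L("y")), (1, 2)),
            ("h2", (L("y"), L("z")), (1, 2)),
        ]
        s = run_solver(members)
        assert set(s.value) == {L("a")}

    def test_no_sequenced_members_empty_assignment(self):
        s = run_solver([])
        assert s.value == {} and not s.seeded


class TestOracleSoundness:
    def test_propagation_sound_against_enumeration(self):
        """Propagated alleles must hold in every satisfying assignment and
        reported conflicts must coincide with unsatisfiable systems."""
        rng = np.random.default_rng(202)
        n_conflict = n_assigned = 0
        for _ in range(300):
            labels, members = random_locus_instance(rng)
            s = run_solver(members)
            all_labels, sols = enumerate_satisfying(labels, members)
            idx = {l: i for i, l in enumerate(all_labels)}
            if s.conflicts:
                n_conflict += 1
                assert len(sols) == 0
            else:
                for label, allele in s.value.items():
                    n_assigned += 1
                    assert len(sols) > 0
                    assert np.all(sols[:, idx[label]] == allele)
        assert n_conflict > 10 and n_assigned > 100  # exercise both branches

    def test_order_independence_of_assignment_and_conflicts(self):
        """Conflict-free closures are confluent: the assignment never depends
        on processing order.  On conflicted loci only the conflict verdict is
        order-independent (the locus is invalidated family-wide either way)."""
        rng = np.random.default_rng(77)
        n_clean = 0
        for _ in range(100):
            _, members = random_locus_instance(rng)
            s1 = run_solver(members)
            perm = list(members)
            rng.shuffle(perm)
            s2 = run_solver(perm)
            assert bool(s1.conflicts) == bool(s2.conflicts)
            if not s1.conflicts:
                n_clean += 1
                assert s1.value == s2.value
        assert n_clean > 25  # both branches exercised


class TestResolveLocus:
    def test_variant_outcomes_on_worked_example(self, demo_data):
        ped, parts = demo_data["pedigree"], demo_data["partitions"]
        lab = pi.recover_all_segments(demo_data["labeling"], ped, parts)
        gm = demo_data["seq_genotypes"]
        asg1, st1, c1 = pi.resolve_locus(0, FAMILY, ped, parts[FAMILY], lab, gm)
        assert st1 is LocusStatus.IMPUTED and not c1
        asg2, st2, c2 = pi.resolve_locus(1, FAMILY, ped, parts[FAMILY], lab, gm)
        assert st2 is LocusStatus.CONFLICT
        assert len(c2) == 1 and c2[0].label == COLORS["pink"]

    def test_between_segments_position(self, demo_data):
        ped = demo_data["pedigree"]
        gm = demo_data["seq_genotypes"]
        part = pi.SegmentPartition(
            FAMILY, "3",
            [pi.Segment("3", 1_000_000, 1_100_000, 0), pi.Segment("3", 1_900_000, 2_000_000, 1)],
        )
        _, st, _ = pi.resolve_locus(0, FAMILY, ped, part, demo_data["labeling"], gm)
        assert st is LocusStatus.BETWEEN_SEGMENTS

    def test_all_het_unresolved(self, demo_data):
        ped, parts = demo_data["pedigree"], demo_data["partitions"]
        gm = demo_data["seq_genotypes"].copy()
        for iid in gm.individuals:  # make every sequenced member heterozygous
            gm.calls[gm.row(iid), 0] = (1, 2)
        _, st, _ = pi.resolve_locus(0, FAMILY, ped, parts[FAMILY], demo_data["labeling"], gm)
        assert st is LocusStatus.UNRESOLVED_ALL_HET


class TestImputeLocus:
    def test_unseen_label_contributes_missing_allele(self, demo_data):
        ped, parts = demo_data["pedigree"], demo_data["partitions"]
        lab = pi.recover_all_segments(demo_data["labeling"], ped, parts)
        asg, st, _ = pi.resolve_locus(
            0, FAMILY, ped, parts[FAMILY], lab, demo_data["seq_genotypes"]
        )
        geno = impute_locus(asg, lab, 0, ["949", "959", "960"])
        for iid in ("949", "959", "960"):  # light-green carriers
            assert sorted(geno[iid]).count(0) == 1

    def test_pointwise_consistency_with_assignment(self):
        rng = np.random.default_rng(5)
        labels = [pi.Label("F", f"f{i}", 1) for i in range(6)]
        assigned = {l: int(rng.integers(1, 3)) for l in labels[:4]}
        asg = pi.AlleleAssignment(0, assigned, set(labels[4:]))
        lab = pi.HaplotypeLabeling()
        targets = []
        for t in range(10):
            pair = tuple(
                None if rng.random() < 0.2 else labels[int(rng.integers(6))]
                for _ in range(2)
            )
            lab.set(f"t{t}", 0, pair)
            targets.append(f"t{t}")
        geno = impute_locus(asg, lab, 0, targets)
        for t in targets:
            pat, mat = lab.get(t, 0)
            expect = tuple(
                assigned.get(l, 0) if l is not None else 0 for l in (pat, mat)
            )
            assert geno[t] == expect


class TestImputeAll:
    def test_noiseless_full_coverage_recovers_truth(self, noiseless_sim):
        ds = noiseless_sim
        res = pi.impute_all(ds.pedigree, ds.partitions, ds.truth_labeling, ds.observed_seq)
        assert not res.conflicts
        truth = ds.truth_genotypes
        for iid in truth.individuals:
            for j in range(len(truth.markers)):
                a, b = res.genotypes.genotype(iid, j)
                if 0 in (a, b):
                    continue  # unseeded or unresolved-label allele
                assert sorted((a, b)) == sorted(truth.genotype(iid, j))

    def test_no_sequenced_individuals_all_unresolved(self, demo_data):
        import dataclasses

        ped = pi.Pedigree(
            dataclasses.replace(i, has_sequence=False) for i in demo_data["pedigree"].individuals
        )
        gm = demo_data["seq_genotypes"]
        res = pi.impute_all(ped, demo_data["partitions"], demo_data["labeling"], gm)
        assert all(st is LocusStatus.UNRESOLVED_ALL_HET for st in res.status.values())
        assert np.all(res.genotypes.calls == 0)

    def test_no_genotypes_emitted_at_conflict_locus(self, demo_data):
        d = demo_data
        lab = pi.recover_all_segments(d["labeling"], d["pedigree"], d["partitions"])
        res = pi.impute_all(d["pedigree"], d["partitions"], lab, d["seq_genotypes"])
        assert res.status[(FAMILY, 1)] is LocusStatus.CONFLICT
        assert np.all(res.genotypes.calls[:, 1, :] == 0)


class TestMaskedAccuracy:
    @staticmethod
    def toy_matrices():
        mm = MarkerMap("1", ["m0", "m1", "m2", "m3"], np.array([100, 200, 300, 400]),
                       ["A"] * 4, ["G"] * 4)
        truth = GenotypeMatrix(["x"], mm, np.array([[[1, 1], [1, 2], [2, 2], [1, 2]]], dtype=np.int8))
        imputed = GenotypeMatrix(["x"], mm, np.array([[[1, 1], [1, 2], [2, 2], [1, 1]]], dtype=np.int8))
        return truth, imputed

    def test_hand_counted_seven_of_eight(self):
        truth, imputed = self.toy_matrices()
        res = ImputationResult(imputed, {}, [], {})
        acc = pi.evaluate_masked_accuracy(truth, res, ["x"])
        assert acc["x"]["n_imputed_alleles"] == 8
        assert acc["x"]["n_correct"] == 7
        assert acc["x"]["accuracy"] == pytest.approx(0.875)

    def test_identical_is_hundred_percent_and_empty_is_undefined(self):
        truth, _ = self.toy_matrices()
        res = ImputationResult(truth.copy(), {}, [], {})
        acc = pi.evaluate_masked_accuracy(truth, res, ["x"])
        assert acc["x"]["accuracy"] == 1.0
        empty = truth.copy()
        empty.calls[:] = 0
        acc0 = pi.evaluate_masked_accuracy(truth, ImputationResult(empty, {}, [], {}), ["x"])
        assert acc0["x"]["accuracy"] is None

    def test_single_allele_scored_against_truth_pair(self):
        truth, imputed = self.toy_matrices()
        imputed.calls[0, 1] = (0, 2)  # one known allele, present in truth (1,2)
        imputed.calls[0, 2] = (0, 1)  # one known allele, absent from truth (2,2)
        res = ImputationResult(imputed, {}, [], {})
        acc = pi.evaluate_masked_accuracy(truth, res, ["x"])
        assert acc["x"]["n_imputed_alleles"] == 6
        assert acc["x"]["n_correct"] == 4  # 2 at m0, 1 at m1, 0 at m2, 1 at m3
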