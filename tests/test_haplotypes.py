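"""Segment partitioning, label bookkeeping and untyped-member recovery."""

import numpy as np
import pytest

import pedimpute as pi
from pedimpute.haplotypes import (
    HaplotypeLabeling,
    Label,
    build_segment_partition,
    load_labeling,
    recover_untyped_haplotypes,
    write_labeling,
)
from pedimpute.pedigree import Individual, MarkerMap, Pedigree, PedigreeError, Sex


def marker_map(n=10, step=1000):
    pos = np.arange(1, n + 1) * step
    return MarkerMap("1", [f"m{j}" for j in range(n)], pos, ["A"] * n, ["G"] * n)


class TestSegmentPartition:
    def test_no_breakpoints_single_segment(self):
        mm = marker_map()
        part = build_segment_partition([], mm, "f1")
        assert len(part.segments) == 1
        assert (part.segments[0].start_bp, part.segments[0].end_bp) == (1000, 10000)

    def test_single_gap_breakpoint_two_segments(self):
        mm = marker_map()
        part = build_segment_partition([("kid", "paternal", 5000, 6000)], mm, "f1")
        assert len(part.segments) == 2
        assert part.segments[0].end_bp == 5000
        assert part.segments[1].start_bp == 6000
        assert all(part.segment_index_for(int(p)) is not None for p in mm.positions)

    def test_random_intervals_tile_every_marker_exactly_once(self):
        rng = np.random.default_rng(3)
        mm = marker_map(60)
        for _ in range(20):
            ivals = []
            for _ in range(3):
                l, r = sorted(rng.choice(mm.positions, 2, replace=False))
                ivals.append(("x", "paternal", int(l), int(r)))
            part = build_segment_partition(ivals, mm, "f1")
            for p in mm.positions:
                p = int(p)
                inside = any(l < p < r for (_, _, l, r) in ivals)
                seg = part.segment_index_for(p)
                if inside:
                    assert seg is None
                else:
                    assert seg is not None
                    s = part.segments[seg]
                    assert s.start_bp <= p <= s.end_bp
            # segments ordered and non-overlapping by construction
            for a, b in zip(part.segments, part.segments[1:]):
                assert a.end_bp < b.start_bp


def recovery_pedigree():
    """Untyped parent P (child of founders g1 x g2) with typed children."""
    return Pedigree(
        [
            Individual("g1", "f1", sex=Sex.MALE, has_chip=True),
            Individual("g2", "f1", sex=Sex.FEMALE, has_chip=True),
            Individual("w", "f1", sex=Sex.FEMALE, has_chip=True),
            Individual("P", "f1", "g1", "g2", sex=Sex.MALE),
            Individual("c1", "f1", "P", "w", has_chip=True),
            Individual("c2", "f1", "P", "w", has_chip=True),
        ]
    )


def base_labeling():
    lab = HaplotypeLabeling()
    for f in ("g1", "g2", "w"):
        lab.set(f, 0, (Label("f1", f, 1), Label("f1", f, 2)))
    return lab


class TestRecovery:
    def test_two_children_with_distinct_labels_recover_both(self):
        ped = recovery_pedigree()
        lab = base_labeling()
        lab.set("c1", 0, (Label("f1", "g1", 1), Label("f1", "w", 1)))
        lab.set("c2", 0, (Label("f1", "g2", 2), Label("f1", "w", 2)))
        out = recover_untyped_haplotypes(lab, ped, 0)
        assert out.get("P", 0) == (Label("f1", "g1", 1), Label("f1", "g2", 2))

    def test_one_child_recovers_exactly_one(self):
        ped = recovery_pedigree()
        lab = base_labeling()
        lab.set("c1", 0, (Label("f1", "g1", 1), Label("f1", "w", 1)))
        out = recover_untyped_haplotypes(lab, ped, 0)
        pair = out.get("P", 0)
        assert pair[0] == Label("f1", "g1", 1)
        assert pair[1] is None

    def test_no_labeled_descendants_stays_unknown(self):
        ped = recovery_pedigree()
        out = recover_untyped_haplotypes(base_labeling(), ped, 0)
        assert out.get("P", 0) == (None, None)

    def test_three_distinct_transmitted_labels_is_an_error(self):
        ped = Pedigree(
            [
                Individual("g1", "f1", sex=Sex.MALE),
                Individual("g2", "f1", sex=Sex.FEMALE),
                Individual("w", "f1", sex=Sex.FEMALE),
                Individual("P", "f1", "g1", "g2", sex=Sex.MALE),
                Individual("c1", "f1", "P", "w"),
                Individual("c2", "f1", "P", "w"),
                Individual("c3", "f1", "P", "w"),
            ]
        )
        lab = base_labeling()
        lab.set("c1", 0, (Label("f1", "g1", 1), None))
        lab.set("c2", 0, (Label("f1", "g1", 2), None))
        lab.set("c3", 0, (Label("f1", "g2", 1), None))
        with pytest.raises(PedigreeError, match="transmission"):
            recover_untyped_haplotypes(lab, ped, 0)

    def test_recovery_is_monotone_and_idempotent(self, noiseless_sim):
        ds = noiseless_sim
        partial = ds.labeling_for_typed()
        ped = ds.pedigree
        seg = 0
        once = recover_untyped_haplotypes(partial, ped, seg)
        twice = recover_untyped_haplotypes(once, ped, seg)
        assert once == twice
        for key, pair in partial.entries.items():
            if key[1] != seg:
                continue
            rec = once.entries[key]
            for s in (0, 1):
                if pair[s] is not None:
                    assert rec[s] == pair[s]

    def test_recovery_is_noop_on_fully_typed_truth(self, noiseless_sim):
        ds = noiseless_sim
        for seg in range(min(3, len(ds.partitions["1"].segments))):
            out = recover_untyped_haplotypes(ds.truth_labeling, ds.pedigree, seg)
            assert out == ds.truth_labeling

    def test_recovery_preserves_transmission_consistency(self, noiseless_sim):
        ds = noiseless_sim
        cfg = ds.config
        import dataclasses
        from pedimpute.simulate import simulate_dataset

        partial_ds = simulate_dataset(dataclasses.replace(cfg, fraction_typed=0.7, seed=13))
        lab = partial_ds.labeling_for_typed()
        assert pi.check_transmission_consistency(lab, partial_ds.pedigree) == []
        out = pi.recover_all_segments(lab, partial_ds.pedigree, partial_ds.partitions)
        assert pi.check_transmission_consistency(out, partial_ds.pedigree) == []


class TestTransmissionConsistency:
    def test_truth_labeling_has_zero_violations(self, noiseless_sim):
        assert pi.check_transmission_consistency(
            noiseless_sim.truth_labeling, noiseless_sim.pedigree
        ) == []

    def test_planted_defect_yields_exactly_one_violation(self, noiseless_sim):
        ds = noiseless_sim
        lab = ds.truth_labeling.copy()
        # a childless non-founder, so only its own paternal meiosis is affected
        child = next(
            i for i in ds.pedigree.individuals
            if not i.is_founder and not ds.pedigree.children_of(i.individual_id)
        )
        bogus = next(
            Label("1", f.individual_id, 1)
            for f in ds.pedigree.founders("1")
            if Label("1", f.individual_id, 1) not in lab.get(child.father_id, 0)
        )
        pat, mat = lab.get(child.individual_id, 0)
        lab.set(child.individual_id, 0, (bogus, mat))
        violations = pi.check_transmission_consistency(lab, ds.pedigree)
        assert len(violations) == 1
        v = violations[0]
        assert (v["child_id"], v["segment"]) == (child.individual_id, 0)

    def test_empty_labeling_has_zero_violations(self, noiseless_sim):
        assert pi.check_transmission_consistency(
            HaplotypeLabeling(), noiseless_sim.pedigree
        ) == []


class TestLabelingIO:
    def test_round_trip_and_founder_normalisation(self, tmp_path, noiseless_sim):
        ds = noiseless_sim
        path = tmp_path / "lab.tsv"
        write_labeling(ds.truth_labeling, ds.pedigree, ds.partitions, path)
        lab, parts = load_labeling(path, ds.pedigree)
        assert lab == ds.truth_labeling
        assert [s.start_bp for s in parts["1"].segments] == [
            s.start_bp for s in ds.partitions["1"].segments
        ]
        fid = ds.pedigree.founders("1")[0].individual_id
        assert lab.get(fid, 0) == (Label("1", fid, 1), Label("1", fid, 2))

    def test_label_naming_nonfounder_is_error(self, tmp_path, noiseless_sim):
        ds = noiseless_sim
        path = tmp_path / "lab.tsv"
        nonfounder = next(
            i.individual_id for i in ds.pedigree.individuals if not i.is_founder
        )
        child = next(
            i for i in ds.pedigree.individuals
            if not i.is_founder and i.individual_id != nonfounder
        )
        lab = ds.truth_labeling.copy()
        lab.set(child.individual_id, 0, (Label("1", nonfounder, 1), None))
        write_labeling(lab, ds.pedigree, ds.partitions, path)
        with pytest.raises(PedigreeError, match="non-founder"):
            load_labeling(path, ds.pedigree)

    def test_transmission_inconsistency_is_a_load_error(self, tmp_path, noiseless_sim):
        ds = noiseless_sim
        path = tmp_path / "lab.tsv"
        lab = ds.truth_labeling.copy()
        child = next(i for i in ds.pedigree.individuals if not i.is_founder)
        founders = ds.pedigree.founders("1")
        bogus_founder = next(
            f.individual_id
            for f in founders
            if Label("1", f.individual_id, 1) not in lab.get(child.father_id, 0)
        )
        lab.set(child.individual_id, 0, (Label("1", bogus_founder, 1), None))
        write_labeling(lab, ds.pedigree, ds.partitions, path)
        with pytest.raises(PedigreeError, match="transmission"):
            load_labeling(path, ds.pedigree)
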