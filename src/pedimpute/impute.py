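"""Per-locus allele-to-haplotype assignment and family-based imputation.

At each sequence-variant locus, within one family and one recombination-free
segment, each founder-haplotype label is a variable over the alleles {1, 2}.
A sequenced homozygote (a, a) fixes both of its labels to ``a``; a sequenced
heterozygote forces its two labels to carry the two different alleles, so
once one of them is known the other follows.  The algorithm is exactly
homozygote seeding followed by unit propagation to closure — no stronger
constraint solving is attempted, so a locus whose heterozygote constraints
are unsatisfiable only through an odd cycle (with no homozygous anchor) is
left unresolved rather than flagged.  Two different alleles forced onto the
same label is a conflict: the signature of a genotype-calling error (or, more
rarely, a wrong inferred inheritance), and the locus is invalidated for the
whole family.

Unit propagation over a binary domain is confluent: the final assignment and
the set of conflicted labels do not depend on processing order.  All
iteration is over sorted identifiers so outputs are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .haplotypes import HaplotypeLabeling, Label, SegmentPartition
from .pedigree import ALT, MISSING, REF, GenotypeMatrix, Pedigree

log = logging.getLogger("pedimpute")


class LocusStatus(Enum):
    IMPUTED = "imputed"
    CONFLICT = "conflict"
    BETWEEN_SEGMENTS = "between_segments"
    UNRESOLVED_ALL_HET = "unresolved_all_het"


@dataclass(frozen=True)
class ConflictRecord:
    """The same haplotype label forced to two different alleles at one locus."""

    family_id: str
    marker_index: int
    label: Label
    allele_a: int
    allele_b: int
    witness_a: str
    witness_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("conflict alleles must differ")


@dataclass
class AlleleAssignment:
    """Partial map label -> allele at one locus; unassigned labels listed."""

    marker_index: int
    assigned: dict[Label, int] = field(default_factory=dict)
    unresolved: set[Label] = field(default_factory=set)
    witnesses: dict[Label, str] = field(default_factory=dict)


@dataclass
class ImputationResult:
    genotypes: GenotypeMatrix
    status: dict[tuple[str, int], LocusStatus]  # (family_id, marker_index)
    conflicts: list[ConflictRecord]
    provenance: dict[tuple[str, int], tuple[Label | None, Label | None]]

    def summary(self) -> dict:
        """Status fractions over (family, locus) cells and over loci.

        The per-locus roll-up uses the precedence imputed > conflict >
        unresolved > between-segments across families, so a locus counts as
        imputed if any family imputed it (between-segments is family-specific
        because each family has its own breakpoints).
        """
        cells = list(self.status.values())
        n_cells = len(cells)
        by_locus: dict[int, set[LocusStatus]] = {}
        for (fam, j), st in self.status.items():
            by_locus.setdefault(j, set()).add(st)
        precedence = [
            LocusStatus.IMPUTED,
            LocusStatus.CONFLICT,
            LocusStatus.UNRESOLVED_ALL_HET,
            LocusStatus.BETWEEN_SEGMENTS,
        ]
        locus_status = {
            j: next(s for s in precedence if s in sts) for j, sts in by_locus.items()
        }
        n_loci = len(locus_status)

        def frac(pool, status):
            n = len(pool)
            return sum(1 for s in pool if s is status) / n if n else 0.0

        return {
            "n_families": len({f for (f, _) in self.status}),
            "n_loci": n_loci,
            "n_cells": n_cells,
            "n_conflicts": len(self.conflicts),
            "cells": {s.value: frac(cells, s) for s in LocusStatus},
            "loci": {s.value: frac(list(locus_status.values()), s) for s in LocusStatus},
        }


# ---------------------------------------------------------------------------
# Per-locus constraint machinery


class _LocusSolver:
    """Seeding + unit propagation for one (family, locus, segment)."""

    def __init__(self, family_id: str, marker_index: int):
        self.family_id = family_id
        self.marker_index = marker_index
        self.value: dict[Label, int] = {}
        self.witness: dict[Label, str] = {}
        self.conflicts: list[ConflictRecord] = []
        self._conflict_keys: set[tuple[Label, int, int]] = set()
        self.seeded = False

    def assign(self, label: Label, allele: int, witness: str) -> bool:
        """Returns True if a new assignment was made."""
        cur = self.value.get(label)
        if cur is None:
            self.value[label] = allele
            self.witness[label] = witness
            return True
        if cur != allele:
            key = (label, min(cur, allele), max(cur, allele))
            if key not in self._conflict_keys:
                self._conflict_keys.add(key)
                self.conflicts.append(
                    ConflictRecord(
                        self.family_id,
                        self.marker_index,
                        label,
                        cur,
                        allele,
                        self.witness[label],
                        witness,
                    )
                )
        return False

    def seed(self, members: list[tuple[str, tuple[Label | None, Label | None], tuple[int, int]]]) -> None:
        for iid, labels, (a, b) in members:
            if a == MISSING or a != b:
                continue
            for lab in labels:
                if lab is not None:
                    self.seeded = True
                    self.assign(lab, a, iid)

    def propagate(self, members) -> None:
        hets = [
            (iid, labels, gt)
            for iid, labels, gt in members
            if gt[0] != MISSING and gt[0] != gt[1]
        ]
        changed = True
        while changed:
            changed = False
            for iid, (pat, mat), (a, b) in hets:
                if pat is None or mat is None:
                    continue  # a single known label is unconstraining for a het
                if pat == mat:
                    # one label on both haplotypes cannot carry two alleles
                    self.assign(pat, a, iid)
                    self.assign(pat, b, iid)
                    continue
                vp, vm = self.value.get(pat), self.value.get(mat)
                if vp is not None and vm is None:
                    changed |= self.assign(mat, b if vp == a else a, iid)
                elif vm is not None and vp is None:
                    changed |= self.assign(pat, b if vm == a else a, iid)
                elif vp is not None and vm is not None and vp == vm:
                    # both forced equal: the het implies the complementary allele
                    self.assign(mat, b if vp == a else a, iid)


def _family_members_at_locus(
    family_id: str,
    pedigree: Pedigree,
    labeling: HaplotypeLabeling,
    seg: int,
    seq_genotypes: GenotypeMatrix,
    marker_index: int,
):
    members = []
    for ind in pedigree.family_members(family_id):
        if not ind.has_sequence or ind.individual_id not in seq_genotypes:
            continue
        labels = labeling.get(ind.individual_id, seg)
        if labels[0] is None and labels[1] is None:
            continue
        gt = seq_genotypes.genotype(ind.individual_id, marker_index)
        members.append((ind.individual_id, labels, gt))
    members.sort(key=lambda m: m[0])
    return members


def seed_from_homozygotes(
    marker_index: int,
    family_id: str,
    segment_index: int,
    labeling: HaplotypeLabeling,
    seq_genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> tuple[AlleleAssignment, list[ConflictRecord]]:
    """Fix each label carried by a sequenced homozygote to that allele."""
    solver = _LocusSolver(family_id, marker_index)
    members = _family_members_at_locus(
        family_id, pedigree, labeling, segment_index, seq_genotypes, marker_index
    )
    solver.seed(members)
    present = labeling.known_labels(family_id, pedigree, segment_index)
    asg = AlleleAssignment(
        marker_index,
        dict(solver.value),
        present - set(solver.value),
        dict(solver.witness),
    )
    return asg, solver.conflicts


def propagate_to_fixed_point(
    seeded: AlleleAssignment,
    marker_index: int,
    family_id: str,
    segment_index: int,
    labeling: HaplotypeLabeling,
    seq_genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> tuple[AlleleAssignment, list[ConflictRecord]]:
    """Unit-propagate heterozygote constraints from a seeded assignment."""
    solver = _LocusSolver(family_id, marker_index)
    solver.value = dict(seeded.assigned)
    solver.witness = dict(seeded.witnesses)
    members = _family_members_at_locus(
        family_id, pedigree, labeling, segment_index, seq_genotypes, marker_index
    )
    solver.propagate(members)
    present = labeling.known_labels(family_id, pedigree, segment_index)
    asg = AlleleAssignment(
        marker_index,
        dict(solver.value),
        present - set(solver.value),
        dict(solver.witness),
    )
    return asg, solver.conflicts


def resolve_locus(
    marker_index: int,
    family_id: str,
    pedigree: Pedigree,
    partition: SegmentPartition,
    labeling: HaplotypeLabeling,
    seq_genotypes: GenotypeMatrix,
) -> tuple[AlleleAssignment, LocusStatus, list[ConflictRecord]]:
    """Seed, propagate, and classify one locus for one family."""
    pos = int(seq_genotypes.markers.positions[marker_index])
    seg = partition.segment_index_for(pos)
    if seg is None:
        return AlleleAssignment(marker_index), LocusStatus.BETWEEN_SEGMENTS, []
    solver = _LocusSolver(family_id, marker_index)
    members = _family_members_at_locus(
        family_id, pedigree, labeling, seg, seq_genotypes, marker_index
    )
    solver.seed(members)
    solver.propagate(members)
    present = labeling.known_labels(family_id, pedigree, seg)
    asg = AlleleAssignment(
        marker_index, dict(solver.value), present - set(solver.value), dict(solver.witness)
    )
    if solver.conflicts:
        return asg, LocusStatus.CONFLICT, solver.conflicts
    if not solver.seeded and not asg.assigned:
        return asg, LocusStatus.UNRESOLVED_ALL_HET, []
    return asg, LocusStatus.IMPUTED, []


def impute_locus(
    assignment: AlleleAssignment,
    labeling: HaplotypeLabeling,
    segment_index: int,
    targets: Iterable[str],
) -> dict[str, tuple[int, int]]:
    """Read each target's genotype off its labels: (paternal, maternal) alleles.

    A label that is unknown or unassigned contributes a missing allele (0)."""
    out = {}
    for iid in sorted(targets):
        pat, mat = labeling.get(iid, segment_index)
        a = assignment.assigned.get(pat, MISSING) if pat is not None else MISSING
        b = assignment.assigned.get(mat, MISSING) if mat is not None else MISSING
        out[iid] = (a, b)
    return out


def impute_all(
    pedigree: Pedigree,
    partitions: Mapping[str, SegmentPartition],
    labeling: HaplotypeLabeling,
    seq_genotypes: GenotypeMatrix,
    chip_genotypes: GenotypeMatrix | None = None,
) -> ImputationResult:
    """Run the full imputation over every locus and family.

    If chip genotypes are supplied, chip/sequence disagreements are first
    reconciled in favour of the chip calls (see :mod:`pedimpute.consistency`)
    before any allele is propagated.  Targets are all pedigree members;
    sequenced individuals keep their observed non-missing calls and have
    their missing calls filled.  No genotype is emitted for a family at a
    conflicted locus.
    """
    if chip_genotypes is not None:
        from .consistency import reconcile_genotypes

        seq_genotypes = reconcile_genotypes(chip_genotypes, seq_genotypes)

    markers = seq_genotypes.markers
    target_ids = [ind.individual_id for ind in pedigree.individuals]
    n_t, n_m = len(target_ids), len(markers)
    calls = np.zeros((n_t, n_m, 2), dtype=np.int8)
    row = {iid: i for i, iid in enumerate(target_ids)}
    status: dict[tuple[str, int], LocusStatus] = {}
    conflicts: list[ConflictRecord] = []
    provenance: dict[tuple[str, int], tuple[Label | None, Label | None]] = {}

    # cache family membership and per-segment member constraint lists
    fam_targets = {
        fam: [i.individual_id for i in pedigree.family_members(fam)]
        for fam in pedigree.family_ids
    }
    for fam in pedigree.family_ids:
        part = partitions.get(fam)
        if part is None:
            continue
        for j in range(n_m):
            asg, st, confl = resolve_locus(
                j, fam, pedigree, part, labeling, seq_genotypes
            )
            status[(fam, j)] = st
            conflicts.extend(confl)
            if st is not LocusStatus.CONFLICT:
                pos = int(markers.positions[j])
                seg = part.segment_index_for(pos)
                if seg is not None:
                    geno = impute_locus(asg, labeling, seg, fam_targets[fam])
                    for iid, (a, b) in geno.items():
                        calls[row[iid], j] = (a, b)
                        provenance[(iid, j)] = labeling.get(iid, seg)
            # observed sequence calls survive (and fill) for sequenced members
            if st is not LocusStatus.CONFLICT:
                for iid in fam_targets[fam]:
                    if pedigree.get(iid).has_sequence and iid in seq_genotypes:
                        a, b = seq_genotypes.genotype(iid, j)
                        if a != MISSING:
                            calls[row[iid], j] = (a, b)
    gm = GenotypeMatrix(target_ids, markers, calls)
    return ImputationResult(gm, status, conflicts, provenance)


def evaluate_masked_accuracy(
    truth: GenotypeMatrix,
    result: ImputationResult,
    masked: Iterable[str],
) -> dict[str, dict]:
    """Proportion of correctly imputed alleles per masked individual.

    Full imputed genotypes are scored by best unordered-pair matching against
    truth; single-allele genotypes score their one allele, correct if present
    in the truth pair.  Loci where the truth call is missing are skipped.
    Zero imputed alleles yields accuracy None (undefined).
    """
    out = {}
    markers = result.genotypes.markers
    for iid in sorted(masked):
        n_imp = n_cor = 0
        for j in range(len(markers)):
            pos = int(markers.positions[j])
            tj = truth.markers.index_of_position(pos)
            if tj is None:
                continue
            t = truth.genotype(iid, tj)
            if t[0] == MISSING:
                continue
            a, b = result.genotypes.genotype(iid, j)
            imp = [x for x in (a, b) if x != MISSING]
            if not imp:
                continue
            n_imp += len(imp)
            if len(imp) == 2:
                ts = sorted(t)
                ims = sorted(imp)
                n_cor += sum(min(ims.count(v), ts.count(v)) for v in {REF, ALT})
            else:
                n_cor += int(imp[0] in t)
        out[iid] = {
            "n_imputed_alleles": n_imp,
            "n_correct": n_cor,
            "accuracy": (n_cor / n_imp) if n_imp else None,
        }
    return out
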