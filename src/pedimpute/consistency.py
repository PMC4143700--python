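"""Chip-vs-sequence genotype concordance and reconciliation.

Array (GWAS) genotypes are treated as ground truth; sequence (WGS) calls at
the markers shared between the two platforms are audited against them.  Each
shared (individual, marker) cell is classified as consistent, missing in the
chip data, missing in the sequence data, or a genuine mismatch.  A/T and C/G
SNPs cannot be disambiguated between strands, so discordances at such markers
are excluded from the mismatch category (missingness classification is
unaffected — strand encoding cannot masquerade as a missing call).
Unambiguous strand flips (e.g. chip C/T vs sequence G/A) are normalised to
the chip strand before comparison.

Reconciliation replaces sequence calls with chip calls wherever the two
disagree or the sequence call is missing; sequence-only markers pass through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .pedigree import ALT, MISSING, REF, GenotypeMatrix, Pedigree, PedigreeError

log = logging.getLogger("pedimpute")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class CellClass(Enum):
    CONSISTENT = "consistent"
    MISSING_IN_GWAS = "missing_in_gwas"
    MISSING_IN_WGS = "missing_in_wgs"
    MISMATCH = "mismatch"
    EXCLUDED_STRAND_AMBIGUOUS = "excluded_strand_ambiguous"


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G pairs are their own reverse complement."""
    return _COMPLEMENT[ref] == alt


def allele_pair_relation(chip: tuple[str, str], seq: tuple[str, str]) -> str | None:
    """How the sequence allele pair maps onto the chip pair.

    Returns 'same', 'swapped' (ref/alt exchanged), 'complement',
    'complement_swapped', or None if irreconcilable."""
    cr, ca = chip
    sr, sa = seq
    if (sr, sa) == (cr, ca):
        return "same"
    if (sr, sa) == (ca, cr):
        return "swapped"
    comp = (_COMPLEMENT[sr], _COMPLEMENT[sa])
    if comp == (cr, ca):
        return "complement"
    if comp == (ca, cr):
        return "complement_swapped"
    return None


def classify_cell(
    chip_call: tuple[int, int],
    seq_call: tuple[int, int],
    ambiguous: bool,
) -> CellClass:
    """Classify one shared cell; calls must already share allele coding."""
    chip_missing = chip_call[0] == MISSING
    seq_missing = seq_call[0] == MISSING
    if chip_missing and seq_missing:
        return CellClass.CONSISTENT
    if chip_missing:
        return CellClass.MISSING_IN_GWAS
    if seq_missing:
        return CellClass.MISSING_IN_WGS
    if sorted(chip_call) == sorted(seq_call):
        return CellClass.CONSISTENT
    if ambiguous:
        return CellClass.EXCLUDED_STRAND_AMBIGUOUS
    return CellClass.MISMATCH


@dataclass
class FamilyCounts:
    n_cells: int = 0
    missing_in_gwas: int = 0
    missing_in_wgs: int = 0
    mismatch: int = 0
    strand_ambiguous_excluded: int = 0
    n_missing_chip: int = 0
    n_missing_seq: int = 0

    @property
    def n_inconsistent(self) -> int:
        return self.missing_in_gwas + self.missing_in_wgs + self.mismatch

    def as_dict(self) -> dict:
        d = {
            "n_cells": self.n_cells,
            "n_inconsistent": self.n_inconsistent,
            "missing_in_gwas": self.missing_in_gwas,
            "missing_in_wgs": self.missing_in_wgs,
            "mismatch": self.mismatch,
            "strand_ambiguous_excluded": self.strand_ambiguous_excluded,
        }
        if self.n_cells:
            d["inconsistency_rate"] = self.n_inconsistent / self.n_cells
            d["missing_rate_gwas"] = self.n_missing_chip / self.n_cells
            d["missing_rate_wgs"] = self.n_missing_seq / self.n_cells
        return d


@dataclass
class ConsistencyReport:
    n_shared_markers: int
    per_family: dict[str, FamilyCounts]
    overall: FamilyCounts
    excluded_families: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in sorted(self.per_family):
            rows.append({"family_id": fam, **self.per_family[fam].as_dict()})
        rows.append({"family_id": "ALL", **self.overall.as_dict()})
        return pd.DataFrame(rows)


def _shared_marker_mapping(chip_gm: GenotypeMatrix, seq_gm: GenotypeMatrix):
    """Match markers by position; yield (chip_idx, seq_idx, flip, ambiguous)."""
    out = []
    for cj, pos in enumerate(chip_gm.markers.positions):
        sj = seq_gm.markers.index_of_position(int(pos))
        if sj is None:
            continue
        chip_pair = (chip_gm.markers.ref[cj], chip_gm.markers.alt[cj])
        seq_pair = (seq_gm.markers.ref[sj], seq_gm.markers.alt[sj])
        rel = allele_pair_relation(chip_pair, seq_pair)
        if rel is None:
            log.warning(
                "marker at %s:%d has irreconcilable alleles %s vs %s; skipped",
                chip_gm.markers.chromosome, pos, chip_pair, seq_pair,
            )
            continue
        flip = rel in ("swapped", "complement_swapped")
        out.append((cj, sj, flip, is_strand_ambiguous(*chip_pair)))
    return out


def _map_seq_call(call: tuple[int, int], flip: bool) -> tuple[int, int]:
    if not flip or call[0] == MISSING:
        return call
    swap = {REF: ALT, ALT: REF}
    a, b = swap[call[0]], swap[call[1]]
    return (a, b) if a <= b else (b, a)


def compare_chip_sequence(
    chip_gm: GenotypeMatrix,
    seq_gm: GenotypeMatrix,
    pedigree: Pedigree,
    normalize_strand: bool = True,
) -> ConsistencyReport:
    """Audit sequence calls against chip calls over shared markers.

    Only sequenced individuals present in both matrices are compared;
    families with no sequenced individuals are excluded from the report.
    """
    mapping = _shared_marker_mapping(chip_gm, seq_gm)
    if not mapping:
        raise PedigreeError("chip and sequence data share no markers")
    per_family: dict[str, FamilyCounts] = {}
    overall = FamilyCounts()
    excluded = []
    for fam in pedigree.family_ids:
        members = [
            i.individual_id
            for i in pedigree.family_members(fam)
            if i.has_sequence and i.individual_id in chip_gm and i.individual_id in seq_gm
        ]
        if not members:
            excluded.append(fam)
            continue
        fc = FamilyCounts()
        for iid in members:
            for cj, sj, flip, ambiguous in mapping:
                chip_call = chip_gm.genotype(iid, cj)
                seq_call = _map_seq_call(
                    seq_gm.genotype(iid, sj), flip and normalize_strand
                )
                cls = classify_cell(chip_call, seq_call, ambiguous)
                fc.n_cells += 1
                fc.n_missing_chip += int(chip_call[0] == MISSING)
                fc.n_missing_seq += int(seq_call[0] == MISSING)
                if cls is CellClass.MISSING_IN_GWAS:
                    fc.missing_in_gwas += 1
                elif cls is CellClass.MISSING_IN_WGS:
                    fc.missing_in_wgs += 1
                elif cls is CellClass.MISMATCH:
                    fc.mismatch += 1
                elif cls is CellClass.EXCLUDED_STRAND_AMBIGUOUS:
                    fc.strand_ambiguous_excluded += 1
        per_family[fam] = fc
        for attr in (
            "n_cells", "missing_in_gwas", "missing_in_wgs", "mismatch",
            "strand_ambiguous_excluded", "n_missing_chip", "n_missing_seq",
        ):
            setattr(overall, attr, getattr(overall, attr) + getattr(fc, attr))
    return ConsistencyReport(len(mapping), per_family, overall, excluded)


def reconcile_genotypes(
    chip_gm: GenotypeMatrix,
    seq_gm: GenotypeMatrix,
    normalize_strand: bool = True,
) -> GenotypeMatrix:
    """Override sequence calls with chip calls at shared markers.

    Where both are called and disagree the chip genotype wins; where the
    sequence call is missing and the chip call is not, the chip call fills
    in.  The result stays on the sequence marker set and allele coding.
    Idempotent: reconciling an already reconciled matrix changes nothing.
    """
    out = seq_gm.copy()
    mapping = _shared_marker_mapping(chip_gm, seq_gm)
    swap = {REF: ALT, ALT: REF, MISSING: MISSING}
    n_replaced = 0
    for iid in seq_gm.individuals:
        if iid not in chip_gm:
            continue
        si = out.row(iid)
        for cj, sj, flip, _ambiguous in mapping:
            chip_call = chip_gm.genotype(iid, cj)
            if chip_call[0] == MISSING:
                continue
            # express the chip call on the sequence coding
            if flip and normalize_strand:
                a, b = swap[chip_call[0]], swap[chip_call[1]]
                chip_on_seq = (a, b) if a <= b else (b, a)
            else:
                chip_on_seq = chip_call
            if tuple(out.calls[si, sj]) != chip_on_seq:
                n_replaced += 1
                out.calls[si, sj] = chip_on_seq
    if n_replaced:
        log.info("reconcile_genotypes: replaced or filled %d sequence calls", n_replaced)
    return out
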