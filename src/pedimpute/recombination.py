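"""Recombination-breakpoint detection from haplotype-label switches.

A switch in an individual's label between consecutive segments on one side
marks a crossover in the corresponding meiosis.  The breakpoint cannot be
placed more precisely than the gap between the last informative marker of
the left segment and the first of the right; that flanking-marker gap is the
reported interval and its length is the breakpoint resolution.

A child's label sequence also changes wherever it copies straight through a
breakpoint that happened one meiosis earlier (the parent's own label switch).
Such inherited switches are not crossovers of the child's meiosis: when the
parent's labels are known at both flanks, a switch that follows a single
parental slot through the parent's own switch is suppressed, so each
crossover is attributed to exactly one meiosis.  Double crossovers falling
inside a single segment (or a single inter-marker gap) are invisible to any
label-based method.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

import numpy as np

from .haplotypes import HaplotypeLabeling, SegmentPartition
from .pedigree import MarkerMap, Pedigree


@dataclass(frozen=True)
class BreakpointInterval:
    family_id: str
    child_id: str
    side: str  # 'paternal' | 'maternal' | 'unknown'
    chromosome: str
    left_bp: int
    right_bp: int

    @property
    def length_bp(self) -> int:
        return self.right_bp - self.left_bp

    def __post_init__(self) -> None:
        if self.left_bp >= self.right_bp:
            raise ValueError("breakpoint interval must have left < right")


def _flanking_positions(
    part: SegmentPartition, seg_left: int, seg_right: int, marker_map: MarkerMap
) -> tuple[int, int]:
    sl, sr = part.segments[seg_left], part.segments[seg_right]
    pos = marker_map.positions
    left = pos[(pos >= sl.start_bp) & (pos <= sl.end_bp)]
    right = pos[(pos >= sr.start_bp) & (pos <= sr.end_bp)]
    lp = int(left[-1]) if len(left) else sl.end_bp
    rp = int(right[0]) if len(right) else sr.start_bp
    return lp, rp


def detect_breakpoints(
    labeling: HaplotypeLabeling,
    partitions: Mapping[str, SegmentPartition],
    pedigree: Pedigree,
    marker_map: MarkerMap,
) -> list[BreakpointInterval]:
    """One interval per label switch attributable to the child's own meiosis."""
    out: list[BreakpointInterval] = []
    for ind in pedigree.individuals:
        if ind.is_founder:
            continue
        part = partitions.get(ind.family_id)
        if part is None:
            continue
        segs = labeling.segments_of(ind.individual_id)
        for s1, s2 in zip(segs, segs[1:]):
            if s2 != s1 + 1:
                continue  # not consecutive: a switch here is unplaceable
            pair_l = labeling.get(ind.individual_id, s1)
            pair_r = labeling.get(ind.individual_id, s2)
            for side_idx, side in ((0, "paternal"), (1, "maternal")):
                ll, lr = pair_l[side_idx], pair_r[side_idx]
                if ll is None or lr is None or ll == lr:
                    continue
                parent_id = ind.father_id if side_idx == 0 else ind.mother_id
                if parent_id is not None and _is_inherited_switch(
                    labeling, parent_id, s1, s2, ll, lr
                ):
                    continue
                lp, rp = _flanking_positions(part, s1, s2, marker_map)
                out.append(
                    BreakpointInterval(
                        ind.family_id, ind.individual_id, side, part.chromosome, lp, rp
                    )
                )
    return out


def _is_inherited_switch(
    labeling: HaplotypeLabeling,
    parent_id: str,
    seg_left: int,
    seg_right: int,
    label_left,
    label_right,
) -> bool:
    """True if the child merely follows one parental slot through the
    parent's own label switch at this boundary (no new crossover)."""
    ppl = labeling.get(parent_id, seg_left)
    ppr = labeling.get(parent_id, seg_right)
    if None in ppl or None in ppr:
        return False  # cannot exclude a new crossover; report it
    for k in (0, 1):
        if ppl[k] == label_left and ppr[k] == label_right:
            return True
    return False


def summarize_resolution(
    intervals: Iterable[BreakpointInterval],
    threshold_bp: int = 20_000,
) -> dict:
    """Side counts, median interval length, and fraction within threshold."""
    intervals = list(intervals)
    n_pat = sum(1 for b in intervals if b.side == "paternal")
    n_mat = sum(1 for b in intervals if b.side == "maternal")
    n_unk = sum(1 for b in intervals if b.side == "unknown")
    lengths = [b.length_bp for b in intervals]
    if not lengths:
        return {
            "empty": True,
            "n_total": 0,
            "n_paternal": 0,
            "n_maternal": 0,
            "n_unknown_side": 0,
            "threshold_bp": threshold_bp,
        }
    return {
        "empty": False,
        "n_total": len(intervals),
        "n_paternal": n_pat,
        "n_maternal": n_mat,
        "n_unknown_side": n_unk,
        "threshold_bp": threshold_bp,
        "fraction_within_threshold": sum(l <= threshold_bp for l in lengths) / len(lengths),
        "median_length_bp": float(median(lengths)),
    }
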