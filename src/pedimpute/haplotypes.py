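"""Family-wide recombination-free segments and founder-haplotype labels.

A family's chromosome is tiled into segments bounded by all recombination
breakpoints observed in that family; within one segment every member carries a
constant ordered pair of founder-haplotype labels (the "colors"): paternal
label first, maternal second.  A label identifies one of a founder's two
chromosomes as ``(founder_id, slot)``; descent of labels through meioses is
identity by descent.  Positions strictly inside a breakpoint interval belong
to no segment ("between segments") and are unimputable there.

Untyped individuals may lack labels; :func:`recover_untyped_haplotypes` pulls
labels back from labeled children (each child's haplotype on the side of the
untyped parent is a haplotype that parent carries), iterated to a fixed point
so a recovered parent can in turn anchor a grandparent.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .pedigree import Pedigree, PedigreeError, MarkerMap

log = logging.getLogger("pedimpute")


class Label(NamedTuple):
    """One of a founder's two haplotypes; the 'color' tracked through descent."""

    family_id: str
    founder_id: str
    slot: int  # 1 or 2

    def __str__(self) -> str:
        return f"{self.founder_id}:{self.slot}"


def parse_label(text: str, family_id: str) -> Label | None:
    if text in ("?", "", ".", None):
        return None
    founder, slot = text.rsplit(":", 1)
    return Label(family_id, founder, int(slot))


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start_bp: int
    end_bp: int
    index: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start after end")


@dataclass
class SegmentPartition:
    """Ordered, non-overlapping segments of one family's chromosome."""

    family_id: str
    chromosome: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end_bp >= b.start_bp:
                raise ValueError("segments overlap or are unordered")
        self._starts = [s.start_bp for s in self.segments]

    def segment_index_for(self, pos: int) -> int | None:
        """Segment index containing ``pos``; None if between segments."""
        i = bisect_right(self._starts, pos) - 1
        if i >= 0 and self.segments[i].start_bp <= pos <= self.segments[i].end_bp:
            return i
        return None


PairEntry = tuple[Label | None, Label | None]  # (paternal, maternal)


class HaplotypeLabeling:
    """Map (individual_id, segment_index) -> ordered (paternal, maternal) labels."""

    def __init__(self, entries: Mapping[tuple[str, int], PairEntry] | None = None):
        self.entries: dict[tuple[str, int], PairEntry] = dict(entries or {})

    def get(self, iid: str, seg: int) -> PairEntry:
        return self.entries.get((iid, seg), (None, None))

    def set(self, iid: str, seg: int, pair: PairEntry) -> None:
        self.entries[(iid, seg)] = pair

    def segments_of(self, iid: str) -> list[int]:
        return sorted(s for (i, s) in self.entries if i == iid)

    def individuals(self) -> list[str]:
        return sorted({i for (i, _) in self.entries})

    def known_labels(self, family_id: str, pedigree: Pedigree, seg: int) -> set[Label]:
        """All labels observed in the family at one segment."""
        out: set[Label] = set()
        for ind in pedigree.family_members(family_id):
            for lab in self.get(ind.individual_id, seg):
                if lab is not None:
                    out.add(lab)
        return out

    def copy(self) -> "HaplotypeLabeling":
        return HaplotypeLabeling(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HaplotypeLabeling) and self.entries == other.entries


# ---------------------------------------------------------------------------
# Segment partition construction


def build_segment_partition(
    breakpoint_intervals: Iterable[tuple[str, str, int, int]],
    marker_map: MarkerMap,
    family_id: str,
) -> SegmentPartition:
    """Tile the marker range into segments cut at every breakpoint interval.

    ``breakpoint_intervals`` are (individual, side, left_bp, right_bp) open
    intervals: markers strictly inside any interval fall between segments.
    Overlapping intervals are merged with a warning.
    """
    ivals = sorted((int(l), int(r)) for (_, _, l, r) in breakpoint_intervals)
    merged: list[tuple[int, int]] = []
    for l, r in ivals:
        if merged and (l, r) == merged[-1]:
            continue  # same inter-marker gap hit by several meioses
        if merged and l < merged[-1][1]:
            log.warning("overlapping breakpoint intervals merged: %s %s", merged[-1], (l, r))
            merged[-1] = (merged[-1][0], max(merged[-1][1], r))
        else:
            merged.append((l, r))

    pos = marker_map.positions
    excluded = [any(l < p < r for (l, r) in merged) for p in pos]
    kept = [i for i in range(len(pos)) if not excluded[i]]
    segments: list[Segment] = []
    run_start = None
    for k, i in enumerate(kept):
        if run_start is None:
            run_start = i
        nxt = kept[k + 1] if k + 1 < len(kept) else None
        split = nxt is not None and any(
            pos[i] <= l < r <= pos[nxt] and (l, r) != (0, 0) for (l, r) in merged
        )
        if nxt is None or split:
            segments.append(
                Segment(marker_map.chromosome, int(pos[run_start]), int(pos[i]), len(segments))
            )
            run_start = None
    return SegmentPartition(family_id, marker_map.chromosome, segments)


# ---------------------------------------------------------------------------
# Labeling I/O


_LABELING_COLS = [
    "family_id",
    "individual_id",
    "segment_index",
    "chrom",
    "start_bp",
    "end_bp",
    "paternal_label",
    "maternal_label",
]


def load_labeling(
    path: str | Path,
    pedigree: Pedigree,
    partitions: Mapping[str, SegmentPartition] | None = None,
) -> tuple[HaplotypeLabeling, dict[str, SegmentPartition]]:
    """Read a labeling TSV; returns the labeling plus per-family partitions.

    If ``partitions`` is None, segment bounds are reconstructed from the file.
    Founder rows are normalised to the canonical (self:1, self:2) pair.
    Labels naming a non-founder, and parent/child transmission
    inconsistencies, are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(_LABELING_COLS) - set(df.columns)
    if missing_cols:
        raise PedigreeError(f"labeling file lacks columns: {sorted(missing_cols)}")

    if partitions is None:
        partitions = {}
        for fam, sub in df.groupby("family_id"):
            segs = (
                sub[["segment_index", "chrom", "start_bp", "end_bp"]]
                .drop_duplicates()
                .astype({"segment_index": int, "start_bp": int, "end_bp": int})
                .sort_values("segment_index")
            )
            partitions[fam] = SegmentPartition(
                fam,
                segs["chrom"].iloc[0],
                [
                    Segment(r.chrom, r.start_bp, r.end_bp, r.segment_index)
                    for r in segs.itertuples(index=False)
                ],
            )
    else:
        partitions = dict(partitions)

    labeling = HaplotypeLabeling()
    founder_ids = {f.individual_id for f in pedigree.founders()}
    for row in df.itertuples(index=False):
        fam = row.family_id
        iid = row.individual_id
        seg = int(row.segment_index)
        if iid not in pedigree:
            raise PedigreeError(f"labeling references unknown individual {iid!r}")
        if iid in founder_ids:
            pair: PairEntry = (Label(fam, iid, 1), Label(fam, iid, 2))
        else:
            pair = (parse_label(row.paternal_label, fam), parse_label(row.maternal_label, fam))
            for lab in pair:
                if lab is not None and lab.founder_id not in founder_ids:
                    raise PedigreeError(
                        f"label {lab} on individual {iid} names a non-founder"
                    )
        labeling.set(iid, seg, pair)
    # all founders carry their own pair on every segment of their family
    for fam, part in partitions.items():
        for f in pedigree.founders(fam):
            for s in part.segments:
                labeling.set(f.individual_id, s.index, (Label(fam, f.individual_id, 1), Label(fam, f.individual_id, 2)))
    violations = check_transmission_consistency(labeling, pedigree)
    if violations:
        v = violations[0]
        raise PedigreeError(
            f"transmission inconsistency at meiosis {v['parent_id']}->{v['child_id']} "
            f"segment {v['segment']}: child label {v['child_label']} not carried by parent"
        )
    return labeling, partitions


def write_labeling(
    labeling: HaplotypeLabeling,
    pedigree: Pedigree,
    partitions: Mapping[str, SegmentPartition],
    path: str | Path,
) -> None:
    rows = []
    for iid in labeling.individuals():
        fam = pedigree.get(iid).family_id
        part = partitions[fam]
        for seg in labeling.segments_of(iid):
            pat, mat = labeling.get(iid, seg)
            s = part.segments[seg]
            rows.append(
                (fam, iid, seg, s.chromosome, s.start_bp, s.end_bp,
                 str(pat) if pat else "?", str(mat) if mat else "?")
            )
    pd.DataFrame(rows, columns=_LABELING_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transmission consistency and recovery


def check_transmission_consistency(
    labeling: HaplotypeLabeling, pedigree: Pedigree
) -> list[dict]:
    """Violations of label descent: a child's known label on one side must be
    one of that parent's two labels whenever the parent's pair is fully known.
    Returns records, never raises."""
    violations = []
    meioses = pedigree.meioses()
    segs_by_child: dict[str, list[int]] = {}
    for (iid, seg) in labeling.entries:
        segs_by_child.setdefault(iid, []).append(seg)
    for parent_id, child_id, side in meioses:
        side_idx = 0 if side == "paternal" else 1
        for seg in segs_by_child.get(child_id, ()):
            child_label = labeling.get(child_id, seg)[side_idx]
            if child_label is None:
                continue
            ppair = labeling.get(parent_id, seg)
            if ppair[0] is None or ppair[1] is None:
                continue  # cannot conclude from a partially known parent
            if child_label not in ppair:
                violations.append(
                    {
                        "parent_id": parent_id,
                        "child_id": child_id,
                        "side": side,
                        "segment": seg,
                        "child_label": child_label,
                    }
                )
    return violations


def _transmitted_labels(
    labeling: HaplotypeLabeling, pedigree: Pedigree, iid: str, seg: int
) -> set[Label]:
    """Distinct labels the children of ``iid`` received from ``iid`` at ``seg``."""
    ind = pedigree.get(iid)
    out: set[Label] = set()
    for child in pedigree.children_of(iid):
        side_idx = 0 if child.father_id == iid else 1
        lab = labeling.get(child.individual_id, seg)[side_idx]
        if lab is not None:
            out.add(lab)
    return out


def recover_untyped_haplotypes(
    labeling: HaplotypeLabeling,
    pedigree: Pedigree,
    segment_index: int,
) -> HaplotypeLabeling:
    """Recover labels of unlabeled individuals from their labeled children.

    For each individual with unknown label slots at the segment, the distinct
    labels transmitted to its children identify the haplotypes it carries:
    two distinct labels recover both, one recovers exactly one, none leaves
    both unknown.  Three or more distinct transmitted labels is a hard
    transmission inconsistency.  Iterates breadth-first sweeps to a fixed
    point so recovery can climb generations.  Monotone: never removes or
    changes a known label.
    """
    lab = labeling.copy()
    seg = segment_index
    changed = True
    while changed:
        changed = False
        for ind in pedigree.individuals:
            iid = ind.individual_id
            pair = lab.get(iid, seg)
            if pair[0] is not None and pair[1] is not None:
                continue
            if ind.is_founder:
                # founder pairs are canonical by definition
                fam = ind.family_id
                new_pair = (Label(fam, iid, 1), Label(fam, iid, 2))
                if new_pair != pair:
                    lab.set(iid, seg, new_pair)
                    changed = True
                continue
            trans = _transmitted_labels(lab, pedigree, iid, seg)
            if len(trans) > 2:
                raise PedigreeError(
                    f"individual {iid} transmits {len(trans)} distinct labels at "
                    f"segment {seg}: transmission inconsistency"
                )
            new = _place_labels(lab, pedigree, ind, seg, pair, trans)
            if new != pair:
                lab.set(iid, seg, new)
                changed = True
    return lab


def _place_labels(
    lab: HaplotypeLabeling,
    pedigree: Pedigree,
    ind,
    seg: int,
    pair: PairEntry,
    trans: set[Label],
) -> PairEntry:
    """Orient recovered labels into (paternal, maternal) slots.

    A label found in the father's known pair goes to the paternal slot and
    vice versa; labels that cannot be oriented fill the remaining unknown
    slot(s) in sorted order (safe: transmission checks compare against the
    pair as a set)."""
    new = list(pair)
    todo = sorted(trans - {l for l in pair if l is not None})
    father_pair = lab.get(ind.father_id, seg) if ind.father_id else (None, None)
    mother_pair = lab.get(ind.mother_id, seg) if ind.mother_id else (None, None)
    for label in list(todo):
        in_f = None not in father_pair and label in father_pair
        in_m = None not in mother_pair and label in mother_pair
        if in_f and not in_m and new[0] is None:
            new[0] = label
            todo.remove(label)
        elif in_m and not in_f and new[1] is None:
            new[1] = label
            todo.remove(label)
    for label in todo:
        if new[0] is None:
            new[0] = label
        elif new[1] is None:
            new[1] = label
    return (new[0], new[1])


def recover_all_segments(
    labeling: HaplotypeLabeling,
    pedigree: Pedigree,
    partitions: Mapping[str, SegmentPartition],
) -> HaplotypeLabeling:
    """Apply recovery on every segment of every family partition."""
    lab = labeling
    for fam in sorted(partitions):
        for s in partitions[fam].segments:
            lab = recover_untyped_haplotypes(lab, pedigree, s.index)
    return lab
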