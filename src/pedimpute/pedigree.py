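"""Pedigree, marker-map and genotype-matrix data model with file I/O.

The containers here are deliberately small and explicit: a :class:`Pedigree`
is a directed family graph whose nodes carry typed/sequenced status flags, a
:class:`MarkerMap` is an ordered list of biallelic SNPs with 1-based base-pair
positions, and a :class:`GenotypeMatrix` stores unordered allele pairs coded
``1`` (reference), ``2`` (alternate) and ``0`` (missing).  Half-calls are
normalised to fully missing on load and multi-allelic records are dropped with
a logged count — the downstream allele-propagation algorithm is defined only
for biallelic SNPs with complete diploid calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("pedimpute")

#: internal allele codes
MISSING, REF, ALT = 0, 1, 2

_BASES = {"A", "C", "G", "T"}


class PedigreeError(ValueError):
    """Raised for structural defects in pedigree or genotype inputs."""


class Sex(Enum):
    UNKNOWN = 0
    MALE = 1
    FEMALE = 2

    @classmethod
    def from_code(cls, code: str | int) -> "Sex":
        try:
            return cls(int(code))
        except (ValueError, KeyError):
            return cls.UNKNOWN


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    has_chip: bool = False
    has_sequence: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Issue:
    """A structured validation finding; ``severity`` is 'error' or 'warning'."""

    kind: str
    severity: str
    message: str
    individual_id: str | None = None
    family_id: str | None = None


class Pedigree:
    """A set of families; individuals keyed by globally unique id.

    Individual ids must be unique across the whole dataset (VCF sample columns
    are flat), which implies uniqueness of (family_id, individual_id).
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self._by_id:
                raise PedigreeError(
                    f"duplicate individual id {ind.individual_id!r}"
                )
            self._by_id[ind.individual_id] = ind
        self._check_references()
        self._check_acyclic()
        self._children: dict[str, list[str]] = {iid: [] for iid in self._by_id}
        for ind in self._by_id.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    self._children[pid].append(ind.individual_id)
        for kids in self._children.values():
            kids.sort()

    # -- construction helpers -------------------------------------------------

    def _check_references(self) -> None:
        for ind in self._by_id.values():
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"{role} id {pid!r} of individual {ind.individual_id!r} "
                        "does not exist in the pedigree"
                    )

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._by_id)
        for ind in self._by_id.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.individual_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"pedigree contains a cycle: {path}")

    # -- accessors ------------------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def individuals(self) -> list[Individual]:
        return [self._by_id[i] for i in sorted(self._by_id)]

    @property
    def family_ids(self) -> list[str]:
        return sorted({i.family_id for i in self._by_id.values()})

    def family_members(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.family_id == family_id]

    def founders(self, family_id: str | None = None) -> list[Individual]:
        inds = self.individuals if family_id is None else self.family_members(family_id)
        return [i for i in inds if i.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [self._by_id[c] for c in self._children[iid]]

    def meioses(self) -> list[tuple[str, str, str]]:
        """(parent_id, child_id, side) triples; side is 'paternal'/'maternal'."""
        out: list[tuple[str, str, str]] = []
        for ind in self.individuals:
            if ind.father_id is not None:
                out.append((ind.father_id, ind.individual_id, "paternal"))
            if ind.mother_id is not None:
                out.append((ind.mother_id, ind.individual_id, "maternal"))
        return out

    def with_status(
        self,
        chip_samples: Iterable[str] = (),
        seq_samples: Iterable[str] = (),
    ) -> "Pedigree":
        """Return a copy with has_chip / has_sequence set from sample lists."""
        chip, seq = set(chip_samples), set(seq_samples)
        return Pedigree(
            replace(
                ind,
                has_chip=ind.individual_id in chip or ind.has_chip,
                has_sequence=ind.individual_id in seq or ind.has_sequence,
            )
            for ind in self.individuals
        )


def validate_pedigree(p: Pedigree) -> list[Issue]:
    """Return structural issues without raising.

    Checks half-specified parent pairs, sex-inconsistent parent roles, and
    sequenced-but-not-chip-typed members (a warning: in chip+sequence study
    designs the sequenced subset is normally nested in the typed subset).
    """
    issues: list[Issue] = []
    for ind in p.individuals:
        if (ind.father_id is None) != (ind.mother_id is None):
            issues.append(
                Issue(
                    "half_specified_parents",
                    "error",
                    f"individual {ind.individual_id} has exactly one parent recorded",
                    ind.individual_id,
                    ind.family_id,
                )
            )
        if ind.father_id is not None and ind.father_id in p:
            f = p.get(ind.father_id)
            if f.sex is Sex.FEMALE:
                issues.append(
                    Issue(
                        "sex_role",
                        "error",
                        f"father {f.individual_id} of {ind.individual_id} is recorded female",
                        f.individual_id,
                        f.family_id,
                    )
                )
        if ind.mother_id is not None and ind.mother_id in p:
            m = p.get(ind.mother_id)
            if m.sex is Sex.MALE:
                issues.append(
                    Issue(
                        "sex_role",
                        "error",
                        f"mother {m.individual_id} of {ind.individual_id} is recorded male",
                        m.individual_id,
                        m.family_id,
                    )
                )
        if ind.has_sequence and not ind.has_chip:
            issues.append(
                Issue(
                    "sequenced_not_typed",
                    "warning",
                    f"individual {ind.individual_id} is sequenced but not chip-typed",
                    ind.individual_id,
                    ind.family_id,
                )
            )
    return issues


# ---------------------------------------------------------------------------
# FAM / status I/O


def load_pedigree(
    path: str | Path,
    status_path: str | Path | None = None,
    chip_samples: Iterable[str] = (),
    seq_samples: Iterable[str] = (),
) -> Pedigree:
    """Load a PLINK FAM file (6 whitespace-delimited columns).

    Typed/sequenced flags are set from ``chip_samples`` / ``seq_samples``
    (normally the sample columns of the genotype files) and may be overridden
    by an explicit status TSV with columns
    family_id, individual_id, has_chip, has_sequence.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fam", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    inds = []
    for row in df.itertuples(index=False):
        father = None if row.father in ("0", None) else row.father
        mother = None if row.mother in ("0", None) else row.mother
        inds.append(
            Individual(
                individual_id=row.iid,
                family_id=row.fam,
                father_id=father,
                mother_id=mother,
                sex=Sex.from_code(row.sex),
            )
        )
    ped = Pedigree(inds).with_status(chip_samples, seq_samples)
    if status_path is not None:
        st = pd.read_csv(status_path, sep="\t", dtype=str)
        chip = set(st.loc[st["has_chip"] == "1", "individual_id"])
        seq = set(st.loc[st["has_sequence"] == "1", "individual_id"])
        ped = Pedigree(
            replace(i, has_chip=i.individual_id in chip, has_sequence=i.individual_id in seq)
            for i in ped.individuals
        )
    return ped


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    """Write a PLINK FAM file (phenotype column fixed at -9)."""
    with open(path, "w") as fh:
        for ind in p.individuals:
            fh.write(
                f"{ind.family_id}\t{ind.individual_id}\t{ind.father_id or 0}\t"
                f"{ind.mother_id or 0}\t{ind.sex.value}\t-9\n"
            )


def write_status(p: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tindividual_id\thas_chip\thas_sequence\n")
        for ind in p.individuals:
            fh.write(
                f"{ind.family_id}\t{ind.individual_id}\t{int(ind.has_chip)}\t"
                f"{int(ind.has_sequence)}\n"
            )


# ---------------------------------------------------------------------------
# Markers and genotypes


@dataclass
class MarkerMap:
    """Ordered biallelic markers on one chromosome, 1-based positions."""

    chromosome: str
    ids: list[str]
    positions: np.ndarray  # int64, strictly increasing
    ref: list[str]
    alt: list[str]
    source: str = "sequence"  # 'chip' or 'sequence'

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) != len(self.ids):
            raise PedigreeError("marker map field lengths differ")
        if np.any(np.diff(self.positions) <= 0):
            raise PedigreeError("marker positions must be strictly increasing")
        self._pos_index = {int(p): i for i, p in enumerate(self.positions)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of_position(self, pos: int) -> int | None:
        return self._pos_index.get(int(pos))

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return MarkerMap(
            self.chromosome,
            [self.ids[i] for i in idx],
            self.positions[idx],
            [self.ref[i] for i in idx],
            [self.alt[i] for i in idx],
            self.source,
        )


@dataclass
class GenotypeMatrix:
    """Unordered diploid calls per (individual, marker).

    ``calls`` has shape (n_individuals, n_markers, 2) with codes 0/1/2
    (missing/ref/alt).  Observed data is either fully called or fully missing;
    imputation output may carry a single known allele (the other slot 0).
    """

    individuals: list[str]
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers), 2):
            raise PedigreeError("genotype matrix dimensions inconsistent")
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    def __contains__(self, iid: str) -> bool:
        return iid in self._row

    def row(self, iid: str) -> int:
        return self._row[iid]

    def genotype(self, iid: str, marker_idx: int) -> tuple[int, int]:
        a, b = self.calls[self._row[iid], marker_idx]
        return int(a), int(b)

    def is_missing(self) -> np.ndarray:
        """Boolean (n_individuals, n_markers): both alleles missing."""
        return np.all(self.calls == MISSING, axis=2)

    def missing_rate_per_marker(self) -> np.ndarray:
        return self.is_missing().mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.markers, self.calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and self.markers.ids == other.markers.ids
            and np.array_equal(self.markers.positions, other.markers.positions)
            and np.array_equal(np.sort(self.calls, axis=2), np.sort(other.calls, axis=2))
        )


def _normalize_pair(a: int, b: int) -> tuple[int, int]:
    """Half-calls collapse to fully missing; pairs stored sorted."""
    if a == MISSING or b == MISSING:
        return MISSING, MISSING
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def load_genotypes(
    path: str | Path,
    pedigree: Pedigree,
    source: str = "sequence",
    marker_map: MarkerMap | None = None,
    on_unknown_sample: str = "warn",
) -> GenotypeMatrix:
    """Load a VCF (``.vcf``) or PLINK PED (``.ped`` + sibling ``.map``).

    Multi-allelic and non-ACGT records are dropped (counts logged).  Samples
    absent from the pedigree are skipped with a warning (``on_unknown_sample=
    'error'`` to hard-fail); zero overlapping samples is always an error.
    """
    path = Path(path)
    if path.suffix == ".ped":
        return _load_ped(path, pedigree, source, marker_map, on_unknown_sample)
    return _load_vcf(path, pedigree, source, on_unknown_sample)


def _resolve_samples(samples: Sequence[str], pedigree: Pedigree, on_unknown: str) -> list[str]:
    keep = []
    for s in samples:
        if s in pedigree:
            keep.append(s)
        elif on_unknown == "error":
            raise PedigreeError(f"sample {s!r} not present in pedigree")
        else:
            log.warning("sample %r not in pedigree; skipped", s)
    if not keep:
        raise PedigreeError("no overlap between genotype file samples and pedigree")
    return keep


def _load_vcf(
    path: Path, pedigree: Pedigree, source: str, on_unknown_sample: str
) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = _resolve_samples(list(vf.header.samples), pedigree, on_unknown_sample)
    sample_idx = {s: i for i, s in enumerate(samples)}
    ids, positions, ref, alt, rows = [], [], [], [], []
    n_multi = n_nonacgt = 0
    chrom = None
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        r, a = rec.ref.upper(), rec.alts[0].upper()
        if r not in _BASES or a not in _BASES:
            n_nonacgt += 1
            continue
        chrom = chrom or rec.chrom
        if rec.chrom != chrom:
            raise PedigreeError("multi-chromosome VCFs are not supported")
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        positions.append(rec.pos)
        ref.append(r)
        alt.append(a)
        row = np.zeros((len(samples), 2), dtype=np.int8)
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                pair = (MISSING, MISSING)
            else:
                pair = _normalize_pair(gt[0] + 1, gt[1] + 1)
            row[sample_idx[s]] = pair
        rows.append(row)
    vf.close()
    if n_multi or n_nonacgt:
        log.info(
            "%s: dropped %d multi-allelic and %d non-ACGT records", path, n_multi, n_nonacgt
        )
    if not rows:
        raise PedigreeError(f"no usable biallelic records in {path}")
    mm = MarkerMap(chrom, ids, np.asarray(positions), ref, alt, source)
    calls = np.stack(rows, axis=1)  # (n_samples, n_markers, 2)
    return GenotypeMatrix(samples, mm, calls)


def _load_ped(
    path: Path,
    pedigree: Pedigree,
    source: str,
    marker_map: MarkerMap | None,
    on_unknown_sample: str,
) -> GenotypeMatrix:
    """Text PLINK PED with sibling .map; alleles as bases or 1/2 codes."""
    if marker_map is None:
        map_path = path.with_suffix(".map")
        mdf = pd.read_csv(
            map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"], dtype=str
        )
        # .map carries no allele columns; alleles are learned from the PED body
        marker_map = MarkerMap(
            str(mdf["chrom"].iloc[0]),
            list(mdf["id"]),
            mdf["pos"].astype(np.int64).to_numpy(),
            ["A"] * len(mdf),
            ["C"] * len(mdf),
            source,
        )
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    n_markers = len(marker_map)
    if df.shape[1] != 6 + 2 * n_markers:
        raise PedigreeError("PED column count does not match marker map")
    samples = _resolve_samples(list(df[1]), pedigree, on_unknown_sample)
    rows = df[df[1].isin(samples)]
    allele_codes = rows.iloc[:, 6:].to_numpy(dtype=object)
    calls = np.zeros((len(rows), n_markers, 2), dtype=np.int8)
    ref, alt = list(marker_map.ref), list(marker_map.alt)
    for j in range(n_markers):
        col = allele_codes[:, 2 * j : 2 * j + 2]
        seen = [x for x in pd.unique(col.ravel()) if x not in ("0", "N", None)]
        if any(x in _BASES for x in seen):
            bases = sorted(x for x in seen if x in _BASES)
            if len(bases) > 2:
                raise PedigreeError(f"marker {marker_map.ids[j]} has >2 alleles in PED")
            code = {bases[0]: REF}
            ref[j] = bases[0]
            if len(bases) == 2:
                code[bases[1]] = ALT
                alt[j] = bases[1]
        else:
            code = {"1": REF, "2": ALT}
        for i in range(len(rows)):
            a = code.get(col[i, 0], MISSING)
            b = code.get(col[i, 1], MISSING)
            calls[i, j] = _normalize_pair(a, b)
    mm = MarkerMap(marker_map.chromosome, marker_map.ids, marker_map.positions, ref, alt, source)
    return GenotypeMatrix(list(rows[1]), mm, calls)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2; a single known allele is emitted as e.g. ``1/.``."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    contig_len = int(gm.markers.positions[-1]) + 1
    header.contigs.add(gm.markers.chromosome, length=contig_len)
    for s in gm.individuals:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for j in range(len(gm.markers)):
        rec = vf.new_record(
            contig=gm.markers.chromosome,
            start=int(gm.markers.positions[j]) - 1,
            stop=int(gm.markers.positions[j]),
            alleles=(gm.markers.ref[j], gm.markers.alt[j]),
            id=gm.markers.ids[j],
        )
        for i, s in enumerate(gm.individuals):
            a, b = gm.calls[i, j]
            rec.samples[s]["GT"] = (
                None if a == MISSING else int(a) - 1,
                None if b == MISSING else int(b) - 1,
            )
        vf.write(rec)
    vf.close()


def filter_by_missing_rate(gm: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Drop markers whose missing-call fraction exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    rates = gm.missing_rate_per_marker()
    keep = rates <= max_missing
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_by_missing_rate: removed %d of %d markers", n_drop, len(keep))
    return GenotypeMatrix(list(gm.individuals), gm.markers.subset(keep), gm.calls[:, keep, :])
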