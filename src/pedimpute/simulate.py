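"""Gene-dropping simulator: pedigrees, truth haplotypes/labels, noisy data.

The generator emulates the structure of a chip+sequence family study: a
multi-generation pedigree in which a subset of members is chip-typed and a
nested subset of the typed members is sequenced.  Founder haplotypes are
drawn site-by-site from per-marker alternate-allele frequencies; each meiosis
receives a Poisson number of crossovers (mean = genetic length in Morgans,
positions uniform along the chromosome, no interference) and the child's
gamete is assembled by copying the parental haplotypes between crossovers.
Founder-haplotype labels descend alongside the alleles, giving truth labels,
a truth segment partition, and truth crossover positions against which the
detection and imputation modules are scored.

The observed chip and sequence matrices are the truth genotypes after a
genotype-error process (with the configured probability a call is replaced by
a uniformly random *different* genotype) and independent per-call
missingness.  All randomness flows from one seeded generator, so a config is
bit-reproducible.

Crossovers that label data cannot expose are excluded from
``truth_crossovers``: an even number of crossovers inside one inter-marker
gap cancels (odd parities are kept with a representative raw position in the
gap), and crossovers outside the marker span have no flanking markers.  The
raw draws are retained in ``raw_crossovers``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import (
    HaplotypeLabeling,
    Label,
    SegmentPartition,
    build_segment_partition,
    write_labeling,
)
from .pedigree import (
    ALT,
    MISSING,
    REF,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    Sex,
    load_genotypes,
    load_pedigree,
    write_pedigree,
    write_status,
    write_vcf,
)

log = logging.getLogger("pedimpute")

_GENOTYPES = [(REF, REF), (REF, ALT), (ALT, ALT)]
_BASE_SET = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for one simulated dataset.

    Defaults mirror the shape of a large chip+sequence family study on one
    chromosome: a three-generation family, ~70% of members chip-typed and
    roughly half of the typed members sequenced, a 2.2-Morgan chromosome,
    2% sequence missingness against 0.7% chip missingness, and a modest
    genotype-calling error rate applied to both platforms.
    """

    n_generations: int = 3
    founder_couples: int = 1
    children_per_couple: int = 3
    n_seq_markers: int = 2000
    n_chip_markers: int = 300
    chromosome: str = "3"
    chromosome_length_bp: int = 200_000_000
    genetic_length_morgans: float = 2.2
    alt_freq_range: tuple[float, float] = (0.1, 0.9)
    allele_freq_beta: tuple[float, float] | None = None
    fraction_typed: float = 0.7
    fraction_sequenced_of_typed: float = 0.48
    genotype_error_rate: float = 0.005
    missing_rate_chip: float = 0.007
    missing_rate_seq: float = 0.02
    seed: int = 0
    family_id: str = "1"
    typed_ids: tuple[str, ...] | None = None
    sequenced_ids: tuple[str, ...] | None = None

    def validate(self) -> None:
        for name in ("fraction_typed", "fraction_sequenced_of_typed",
                     "genotype_error_rate", "missing_rate_chip", "missing_rate_seq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_seq_markers < 1 or self.n_chip_markers < 1:
            raise ValueError("marker counts must be >= 1")
        if self.n_chip_markers > self.n_seq_markers:
            raise ValueError("chip markers must be a subset of sequence markers")
        if self.n_generations < 2 or self.children_per_couple < 1 or self.founder_couples < 1:
            raise ValueError("pedigree spec invalid")
        if self.genetic_length_morgans < 0:
            raise ValueError("genetic length must be non-negative")


@dataclass
class MeiosisRecord:
    parent_id: str
    child_id: str
    side: str
    raw_positions: list[float]
    effective: list[tuple[int, float]]  # (left marker index of gap, position)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pedigree: Pedigree
    seq_map: MarkerMap
    chip_map: MarkerMap
    chip_marker_indices: np.ndarray
    hap_alleles: dict[str, np.ndarray]       # iid -> (2, n_seq) codes 1/2
    hap_labels: dict[str, list[list[Label]]]  # iid -> [pat labels, mat labels] per marker
    truth_labeling: HaplotypeLabeling
    partitions: dict[str, SegmentPartition]
    meioses: list[MeiosisRecord]
    observed_seq: GenotypeMatrix
    observed_chip: GenotypeMatrix
    truth_genotypes: GenotypeMatrix           # all individuals x seq markers
    error_sites: list[tuple[str, str, int]]   # (matrix, iid, marker_index)
    missing_sites: list[tuple[str, str, int]]
    masked: set[str] = field(default_factory=set)

    @property
    def truth_crossovers(self) -> list[dict]:
        """Label-visible crossovers with their flanking-marker interval."""
        pos = self.seq_map.positions
        out = []
        for m in self.meioses:
            for gap, x in m.effective:
                out.append(
                    {
                        "parent_id": m.parent_id,
                        "child_id": m.child_id,
                        "side": m.side,
                        "position": float(x),
                        "left_bp": int(pos[gap]),
                        "right_bp": int(pos[gap + 1]),
                    }
                )
        return out

    def labeling_for_typed(self) -> HaplotypeLabeling:
        """Truth labels restricted to chip-typed members (what an
        SNP-based haplotyping step could actually deliver)."""
        keep = {
            i.individual_id for i in self.pedigree.individuals if i.has_chip
        }
        return HaplotypeLabeling(
            {k: v for k, v in self.truth_labeling.entries.items() if k[0] in keep}
        )


# ---------------------------------------------------------------------------
# Pedigree construction


def build_family(
    n_generations: int,
    founder_couples: int,
    children_per_couple: int,
    family_id: str,
) -> Pedigree:
    """Regular multi-generation family: every child of a non-final generation
    marries a new founder spouse and has ``children_per_couple`` children."""
    inds: list[Individual] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return str(counter[0])

    couples: list[tuple[str, str]] = []
    for _ in range(founder_couples):
        f, m = new_id(), new_id()
        inds.append(Individual(f, family_id, sex=Sex.MALE))
        inds.append(Individual(m, family_id, sex=Sex.FEMALE))
        couples.append((f, m))
    for gen in range(1, n_generations):
        next_couples = []
        for father, mother in couples:
            for k in range(children_per_couple):
                cid = new_id()
                sex = Sex.MALE if k % 2 == 0 else Sex.FEMALE
                inds.append(
                    Individual(cid, family_id, father_id=father, mother_id=mother, sex=sex)
                )
                if gen < n_generations - 1:
                    sid = new_id()
                    spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                    inds.append(Individual(sid, family_id, sex=spouse_sex))
                    next_couples.append(
                        (cid, sid) if sex is Sex.MALE else (sid, cid)
                    )
        couples = next_couples
    return Pedigree(inds)


def _generation_order(p: Pedigree) -> list[str]:
    """Parents before children."""
    depth: dict[str, int] = {}

    def d(iid: str) -> int:
        if iid not in depth:
            ind = p.get(iid)
            depth[iid] = 0 if ind.is_founder else 1 + max(d(ind.father_id), d(ind.mother_id))
        return depth[iid]

    return sorted((i.individual_id for i in p.individuals), key=lambda i: (d(i), i))


# ---------------------------------------------------------------------------
# Core generator


def _unique_sorted_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length, size=int(n * 1.2) + 10))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    config.validate()
    rng = np.random.default_rng(config.seed)
    fam = config.family_id
    ped = build_family(
        config.n_generations, config.founder_couples, config.children_per_couple, fam
    )
    all_ids = [i.individual_id for i in ped.individuals]

    # typed / sequenced status
    if config.typed_ids is not None:
        typed = list(config.typed_ids)
    else:
        n_typed = max(1, round(config.fraction_typed * len(all_ids)))
        typed = sorted(rng.choice(sorted(all_ids), size=n_typed, replace=False))
    if config.sequenced_ids is not None:
        sequenced = list(config.sequenced_ids)
        if not set(sequenced) <= set(typed):
            raise ValueError("sequenced_ids must be a subset of typed ids")
    else:
        n_seq = max(1, round(config.fraction_sequenced_of_typed * len(typed)))
        sequenced = sorted(rng.choice(sorted(typed), size=n_seq, replace=False))
    ped = ped.with_status(typed, sequenced)

    # markers
    positions = _unique_sorted_positions(rng, config.n_seq_markers, config.chromosome_length_bp)
    ref_idx = rng.integers(0, 4, size=config.n_seq_markers)
    alt_shift = rng.integers(1, 4, size=config.n_seq_markers)
    ref = list(_BASE_SET[ref_idx])
    alt = list(_BASE_SET[(ref_idx + alt_shift) % 4])
    seq_map = MarkerMap(
        config.chromosome,
        [f"var{j + 1}" for j in range(config.n_seq_markers)],
        positions,
        ref,
        alt,
        "sequence",
    )
    if config.allele_freq_beta is not None:
        a, b = config.allele_freq_beta
        freqs = rng.beta(a, b, size=config.n_seq_markers)
    else:
        lo, hi = config.alt_freq_range
        freqs = rng.uniform(lo, hi, size=config.n_seq_markers)

    # founder haplotypes and gene dropping
    n_m = config.n_seq_markers
    hap_alleles: dict[str, np.ndarray] = {}
    hap_labels: dict[str, list[list[Label]]] = {}
    meiosis_records: list[MeiosisRecord] = []
    for iid in _generation_order(ped):
        ind = ped.get(iid)
        if ind.is_founder:
            haps = np.where(rng.random((2, n_m)) < freqs, ALT, REF).astype(np.int8)
            hap_alleles[iid] = haps
            hap_labels[iid] = [
                [Label(fam, iid, 1)] * n_m,
                [Label(fam, iid, 2)] * n_m,
            ]
        else:
            child_haps = np.empty((2, n_m), dtype=np.int8)
            child_labels: list[list[Label]] = [[], []]
            for hap_idx_child, (pid, side) in enumerate(
                ((ind.father_id, "paternal"), (ind.mother_id, "maternal"))
            ):
                src, rec = _drop_gamete(rng, config, positions, pid, iid, side)
                child_haps[hap_idx_child] = hap_alleles[pid][src, np.arange(n_m)]
                plabels = hap_labels[pid]
                child_labels[hap_idx_child] = [
                    plabels[src[j]][j] for j in range(n_m)
                ]
                meiosis_records.append(rec)
            hap_alleles[iid] = child_haps
            hap_labels[iid] = child_labels

    # family-wide partition from every label-visible crossover
    bp_intervals = [
        (m.child_id, m.side, int(positions[g]), int(positions[g + 1]))
        for m in meiosis_records
        for (g, _x) in m.effective
    ]
    partition = build_segment_partition(bp_intervals, seq_map, fam)
    partitions = {fam: partition}

    truth_labeling = HaplotypeLabeling()
    for iid in all_ids:
        for seg in partition.segments:
            j = int(np.searchsorted(positions, seg.start_bp))
            truth_labeling.set(
                iid, seg.index, (hap_labels[iid][0][j], hap_labels[iid][1][j])
            )

    # truth genotype matrices
    truth_calls = np.zeros((len(all_ids), n_m, 2), dtype=np.int8)
    for i, iid in enumerate(sorted(all_ids)):
        pair = np.sort(hap_alleles[iid], axis=0).T
        truth_calls[i] = pair
    truth_genotypes = GenotypeMatrix(sorted(all_ids), seq_map, truth_calls)

    chip_idx = np.sort(rng.choice(n_m, size=config.n_chip_markers, replace=False))
    chip_map = MarkerMap(
        config.chromosome,
        [seq_map.ids[j] for j in chip_idx],
        positions[chip_idx],
        [ref[j] for j in chip_idx],
        [alt[j] for j in chip_idx],
        "chip",
    )

    seq_ids = sorted(sequenced)
    chip_ids = sorted(typed)
    obs_seq_calls = np.stack([truth_calls[truth_genotypes.row(i)] for i in seq_ids])
    obs_chip_calls = np.stack(
        [truth_calls[truth_genotypes.row(i)][chip_idx] for i in chip_ids]
    )
    error_sites: list[tuple[str, str, int]] = []
    missing_sites: list[tuple[str, str, int]] = []
    _inject_noise(rng, obs_seq_calls, seq_ids, "sequence",
                  config.genotype_error_rate, config.missing_rate_seq,
                  error_sites, missing_sites)
    _inject_noise(rng, obs_chip_calls, chip_ids, "chip",
                  config.genotype_error_rate, config.missing_rate_chip,
                  error_sites, missing_sites)
    observed_seq = GenotypeMatrix(seq_ids, seq_map, obs_seq_calls)
    observed_chip = GenotypeMatrix(chip_ids, chip_map, obs_chip_calls)

    return SyntheticDataset(
        config=config,
        pedigree=ped,
        seq_map=seq_map,
        chip_map=chip_map,
        chip_marker_indices=chip_idx,
        hap_alleles=hap_alleles,
        hap_labels=hap_labels,
        truth_labeling=truth_labeling,
        partitions=partitions,
        meioses=meiosis_records,
        observed_seq=observed_seq,
        observed_chip=observed_chip,
        truth_genotypes=truth_genotypes,
        error_sites=error_sites,
        missing_sites=missing_sites,
    )


def _drop_gamete(
    rng: np.random.Generator,
    config: SimulationConfig,
    positions: np.ndarray,
    parent_id: str,
    child_id: str,
    side: str,
) -> tuple[np.ndarray, MeiosisRecord]:
    """One meiosis: crossover draw plus the per-marker source-haplotype index."""
    n_x = rng.poisson(config.genetic_length_morgans)
    xpos = np.sort(rng.uniform(1.0, float(config.chromosome_length_bp), size=n_x))
    start = int(rng.integers(2))
    src = (start + np.searchsorted(xpos, positions)) % 2
    effective = []
    flips = np.flatnonzero(src[:-1] != src[1:])
    for g in flips:
        in_gap = xpos[(xpos > positions[g]) & (xpos < positions[g + 1])]
        effective.append((int(g), float(in_gap[0])))
    rec = MeiosisRecord(parent_id, child_id, side, [float(x) for x in xpos], effective)
    return src.astype(np.intp), rec


def _inject_noise(
    rng: np.random.Generator,
    calls: np.ndarray,
    ids: list[str],
    matrix_name: str,
    error_rate: float,
    missing_rate: float,
    error_sites: list,
    missing_sites: list,
) -> None:
    n_i, n_m, _ = calls.shape
    if error_rate > 0:
        hit = rng.random((n_i, n_m)) < error_rate
        for i, j in zip(*np.nonzero(hit)):
            cur = tuple(calls[i, j])
            alternatives = [g for g in _GENOTYPES if g != cur]
            calls[i, j] = alternatives[rng.integers(len(alternatives))]
            error_sites.append((matrix_name, ids[i], int(j)))
    if missing_rate > 0:
        miss = rng.random((n_i, n_m)) < missing_rate
        for i, j in zip(*np.nonzero(miss)):
            calls[i, j] = (MISSING, MISSING)
            missing_sites.append((matrix_name, ids[i], int(j)))


def mask_individuals(ds: SyntheticDataset, ids: set[str] | list[str]) -> SyntheticDataset:
    """Set every observed chip and sequence call of ``ids`` to missing.

    Truth is retained for evaluation; the masked set is recorded."""
    ids = set(ids)
    unknown = ids - {i.individual_id for i in ds.pedigree.individuals}
    if unknown:
        raise ValueError(f"cannot mask unknown individuals: {sorted(unknown)}")
    obs_seq = ds.observed_seq.copy()
    obs_chip = ds.observed_chip.copy()
    for iid in ids:
        if iid in obs_seq:
            obs_seq.calls[obs_seq.row(iid)] = MISSING
        if iid in obs_chip:
            obs_chip.calls[obs_chip.row(iid)] = MISSING
    return replace(ds, observed_seq=obs_seq, observed_chip=obs_chip, masked=ds.masked | ids)


# ---------------------------------------------------------------------------
# Dataset I/O


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict:
    """Emit FAM, status TSV, chip/sequence VCFs, truth labeling TSV, truth
    tables and a manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "fam": "pedigree.fam",
        "status": "status.tsv",
        "chip_vcf": "chip.vcf",
        "seq_vcf": "sequence.vcf",
        "labeling": "truth_labeling.tsv",
        "truth_vcf": "truth_genotypes.vcf",
        "crossovers": "truth_crossovers.tsv",
    }
    write_pedigree(ds.pedigree, directory / files["fam"])
    write_status(ds.pedigree, directory / files["status"])
    write_vcf(ds.observed_chip, directory / files["chip_vcf"])
    write_vcf(ds.observed_seq, directory / files["seq_vcf"])
    write_labeling(ds.truth_labeling, ds.pedigree, ds.partitions, directory / files["labeling"])
    write_vcf(ds.truth_genotypes, directory / files["truth_vcf"])
    pd.DataFrame(ds.truth_crossovers).to_csv(
        directory / files["crossovers"], sep="\t", index=False
    )
    cfg = asdict(ds.config)
    manifest = {"config": cfg, "files": files, "masked": sorted(ds.masked)}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(directory: str | Path):
    """Reload the files written by :func:`write_dataset`.

    Returns (pedigree, chip GenotypeMatrix, sequence GenotypeMatrix, truth
    labeling, partitions, truth GenotypeMatrix, manifest)."""
    from .haplotypes import load_labeling

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    ped = load_pedigree(directory / files["fam"], status_path=directory / files["status"])
    chip = load_genotypes(directory / files["chip_vcf"], ped, source="chip")
    seq = load_genotypes(directory / files["seq_vcf"], ped, source="sequence")
    labeling, partitions = load_labeling(directory / files["labeling"], ped)
    truth = load_genotypes(directory / files["truth_vcf"], ped, source="sequence")
    return ped, chip, seq, labeling, partitions, truth, manifest
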