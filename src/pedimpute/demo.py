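"""A small worked example: one family, one segment, two sequence variants.

Nine members of a three-couple family; four are sequenced (974, 940, 956,
939), three are chip-typed only (938, 959, 960) and two are completely
untyped (949, 957).  The haplotype colors are founder-anchored labels:

========  ==========  =====================
color     label       carried by
========  ==========  =====================
pink      974:1       974, 940, 939, 960
dark blue 974:2       974, 956, 959
lt. blue  938:1       938, 940
yellow    938:2       938, 956 (and 957, recoverable from his one child)
green     949:1       949, 939, 956
lt. green 949:2       949, 959, 960
========  ==========  =====================

At variant 1 the homozygote 974 = (1,1) anchors pink and dark blue to allele
1; propagation through the heterozygotes 940, 956 and 939 resolves light
blue, yellow and green to allele 2; light green never occurs in a sequenced
member, so its carriers are imputed with exactly one missing allele.  At
variant 2 the homozygotes 974 = (2,2) and 939 = (1,1) force different
alleles onto pink: a conflict, the signature of a genotype-calling error.
"""

from __future__ import annotations

import numpy as np

from .haplotypes import HaplotypeLabeling, Label, Segment, SegmentPartition
from .pedigree import GenotypeMatrix, Individual, MarkerMap, Pedigree, Sex

FAMILY = "21"

COLORS = {
    "pink": Label(FAMILY, "974", 1),
    "dark_blue": Label(FAMILY, "974", 2),
    "light_blue": Label(FAMILY, "938", 1),
    "yellow": Label(FAMILY, "938", 2),
    "green": Label(FAMILY, "949", 1),
    "light_green": Label(FAMILY, "949", 2),
}


def example_pedigree() -> Pedigree:
    c = COLORS  # noqa: F841 - documented mapping above
    return Pedigree(
        [
            Individual("974", FAMILY, sex=Sex.MALE, has_chip=True, has_sequence=True),
            Individual("938", FAMILY, sex=Sex.FEMALE, has_chip=True),
            Individual("949", FAMILY, sex=Sex.FEMALE),
            Individual("957", FAMILY, "974", "938", sex=Sex.MALE),
            Individual("940", FAMILY, "974", "938", sex=Sex.MALE, has_chip=True, has_sequence=True),
            Individual("956", FAMILY, "957", "949", sex=Sex.FEMALE, has_chip=True, has_sequence=True),
            Individual("939", FAMILY, "974", "949", sex=Sex.MALE, has_chip=True, has_sequence=True),
            Individual("959", FAMILY, "974", "949", sex=Sex.MALE, has_chip=True),
            Individual("960", FAMILY, "974", "949", sex=Sex.FEMALE, has_chip=True),
        ]
    )


def example_partition() -> SegmentPartition:
    return SegmentPartition(FAMILY, "3", [Segment("3", 1_000_000, 2_000_000, 0)])


def example_labeling(include_untyped: bool = False) -> HaplotypeLabeling:
    """Labels for chip-typed members; pass ``include_untyped=True`` for the
    full truth (what recovery should reconstruct for 949 and 957)."""
    c = COLORS
    lab = HaplotypeLabeling()
    lab.set("974", 0, (c["pink"], c["dark_blue"]))
    lab.set("938", 0, (c["light_blue"], c["yellow"]))
    lab.set("940", 0, (c["pink"], c["light_blue"]))
    lab.set("956", 0, (c["yellow"], c["green"]))
    lab.set("939", 0, (c["pink"], c["green"]))
    lab.set("959", 0, (c["dark_blue"], c["light_green"]))
    lab.set("960", 0, (c["pink"], c["light_green"]))
    if include_untyped:
        lab.set("949", 0, (c["green"], c["light_green"]))
        lab.set("957", 0, (None, c["yellow"]))
    return lab


def example_sequence_genotypes() -> GenotypeMatrix:
    """Two variants inside the segment; codes 1/2 are ref/alt, 0 missing."""
    mm = MarkerMap("3", ["var1", "var2"], np.array([1_200_000, 1_600_000]),
                   ["A", "C"], ["G", "T"], "sequence")
    samples = ["939", "940", "956", "974"]
    calls = np.zeros((4, 2, 2), dtype=np.int8)
    gt = {
        ("974", 0): (1, 1), ("940", 0): (1, 2), ("956", 0): (1, 2), ("939", 0): (1, 2),
        ("974", 1): (2, 2), ("939", 1): (1, 1), ("940", 1): (0, 0), ("956", 1): (0, 0),
    }
    for (iid, j), pair in gt.items():
        calls[samples.index(iid), j] = pair
    return GenotypeMatrix(samples, mm, calls)


def example_dataset() -> dict:
    """Everything needed to run the example end to end."""
    return {
        "pedigree": example_pedigree(),
        "partitions": {FAMILY: example_partition()},
        "labeling": example_labeling(),
        "seq_genotypes": example_sequence_genotypes(),
        "colors": COLORS,
    }
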