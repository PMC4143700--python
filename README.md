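# pedimpute

Family-based imputation of sequence variants through pedigree haplotype
labels — with genotype-conflict detection, chip/sequence reconciliation,
recombination-breakpoint mapping, and a gene-dropping simulator for
end-to-end validation.

## The problem

Sequencing every member of a large pedigree is expensive; many family
studies instead sequence a subset of members and genotype the rest (or only
some of the rest) on SNP chips. Because relatives share long chromosomal
segments identical by descent (IBD), a variant observed in one sequenced
member can be transferred to every unsequenced relative who carries the same
founder haplotype over that position.

`pedimpute` operates on **founder-haplotype labels**: within each family,
each chromosome of each founder gets a label (founder, slot ∈ {1,2}) — the
"colors" of an IBD painting. The chromosome is tiled into
**recombination-free segments** bounded by all crossovers observed in the
family; within one segment every member carries a constant ordered pair of
labels (paternal, maternal). Such labelings come from an upstream
pedigree-haplotyping step run on the chip data, or from the bundled
simulator's truth.

Given labels and sequence genotypes, the per-locus algorithm is:

1. **Homozygote seeding.** If a sequenced member with labels (hᵢ, hⱼ) is
   homozygous (a, a), then allele(hᵢ) = allele(hⱼ) = a.
2. **Unit propagation.** For a sequenced heterozygote with labels (hᵢ, hⱼ),
   the two labels carry the two different alleles, so once one is known the
   other follows; repeat to closure.
3. **Conflict detection.** If the same label is forced to two different
   alleles, the locus is flagged for the whole family and no genotype is
   emitted there — in practice the signature of a sequence genotype-calling
   error.
4. **Imputation.** Every family member's genotype at the locus is read off
   its two labels; an unresolved label contributes a missing allele.

Around this core the package provides:

- **recovery of untyped members' labels** from their children (each child's
  haplotype on the side of an untyped parent is a haplotype that parent
  carries; two distinct transmitted labels recover both haplotypes, one
  recovers one), iterated to a fixed point across generations;
- **chip/sequence concordance**: every shared (individual, marker) cell is
  classified consistent / missing-in-chip / missing-in-sequence / mismatch,
  with A/T and C/G SNPs excluded from the mismatch class (their strand
  cannot be disambiguated) and unambiguous strand flips normalised;
  reconciliation replaces discordant or missing sequence calls with the chip
  call before imputation;
- **recombination breakpoints**: a label switch between consecutive segments
  on one side of a meiosis marks a crossover; its position is bounded by the
  flanking informative markers, and that gap is the reported resolution;
- **a gene-dropping simulator**: founder haplotypes drawn from allele
  frequencies, Poisson crossovers (no interference), labels and alleles
  dropped through the pedigree, configurable genotype error and missingness,
  and masking for accuracy studies.

## Worked example

`examples/worked_example.py` runs the bundled nine-member family with two
sequence variants:

```
recovered 949: ['949:1', '949:2']
recovered 957: ['?', '938:2']
variant 1: imputed
variant 2: conflict
conflict on 974:1: allele 1 (from 939) vs 2 (from 974)

imputed genotypes at variant 1 (0 = missing allele):
  949: (2, 0)
  957: (0, 1)
  959: (1, 0)
  960: (1, 0)
  938: (2, 1)
```

Both haplotypes of the untyped founder 949 are anchored through her three
children; the untyped non-founder 957 has only one child, so exactly one of
his haplotypes is recovered. At variant 1, the homozygote 974 = (1,1) seeds
two labels and propagation resolves three more; the one haplotype never seen
in a sequenced member leaves its carriers (949, 959, 960) with one missing
allele each. At variant 2, two homozygotes force different alleles onto the
same label — the locus is reported as a conflict and no genotypes are
emitted for the family there.

The other example scripts demonstrate masking-based accuracy evaluation
(`simulate_mask_evaluate.py`), breakpoint detection
(`recombination_breakpoints.py`) and the concordance audit
(`chip_seq_concordance.py`).

## Command line

A thin CLI wraps the same functions:

```sh
pedimpute simulate --seed 17 --out sim/
pedimpute impute   --fam sim/pedigree.fam --status sim/status.tsv \
                   --chip-vcf sim/chip.vcf --seq-vcf sim/sequence.vcf \
                   --labeling sim/truth_labeling.tsv --out run/
pedimpute check ... ; pedimpute recomb ... ; pedimpute evaluate ...
```

`impute` writes an imputed VCF (single known alleles as `1/.`), a per-locus
status TSV (imputed / conflict / between-segments / unresolved), a conflicts
TSV and a summary JSON. Markers with a missing-call rate above 5% are
dropped by default (`--max-missing`).

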