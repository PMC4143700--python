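# Methods

## Model and assumptions

The package treats imputation in pedigrees as a deterministic constraint
problem over identity-by-descent (IBD) haplotype labels rather than a
probabilistic one. Its assumptions:

- **Biallelic SNPs only.** Alleles are coded 1 (reference) and 2
  (alternate), 0 for missing; multi-allelic and non-ACGT records are dropped
  at load time with a logged count. Half-calls (`./1`) are collapsed to
  fully missing: the propagation rules are defined for complete diploid
  calls, and a half-call treated as a constraint could seed a spurious
  allele from a miscalled site.
- **Labels are correct where given.** The haplotype labeling (from an
  upstream pedigree-haplotyping step on chip data, or simulator truth) is
  taken as ground truth; a conflict therefore indicts the sequence genotype
  rather than the inheritance, which matches the empirical situation where
  chip calls are far more reliable than early sequence calls. Wrong labels
  surface as conflicts too and cannot be distinguished from calling errors
  by this method.
- **Family-wide segments.** Segments are bounded by *all* crossovers
  observed in a family, so one member's recombination shortens everyone's
  segments and positions strictly inside a breakpoint interval are
  unimputable ("between segments") for the whole family. Per-individual
  segmentations would drop fewer variants but are out of scope.
- **Autosomal inheritance.** Non-autosomal markers are accepted but no
  X-specific inheritance model is applied.

## The per-locus algorithm and its strength

At one locus, within one family and segment, each label is a variable over
{1, 2}. Sequenced homozygotes fix their known labels; sequenced
heterozygotes impose an inequality between their two labels. The solver is
exactly **homozygote seeding followed by unit propagation to closure** — no
stronger inference. An odd cycle of heterozygote inequalities with no
homozygous anchor is unsatisfiable, but the solver deliberately does not
detect it: such loci end unresolved instead of conflicted. The brute-force
enumeration oracle in the test suite therefore checks *soundness* (every
propagated allele is entailed by all satisfying assignments; every reported
conflict implies unsatisfiability), not completeness beyond unit
propagation. Rationale: the simple two-step procedure is the method being
validated, and restricting conflicts to homozygote-rooted contradictions
keeps the conflict signal interpretable as a calling-error detector.

Unit propagation over a binary domain is confluent, so on conflict-free loci
the final assignment is independent of processing order; the implementation
additionally iterates in sorted-identifier order so all outputs are
byte-stable. Once a label is conflicted its first-assigned value is
retained, so *downstream* values at a conflicted locus can depend on order —
irrelevant in practice because a conflict invalidates the locus for the
whole family and no genotypes are emitted there. Whether a conflicted locus
could still be imputed for family members not touching the conflicted label
is an open design point; the family-wide invalidation implemented here is
the conservative reading.

Locus classification: `BETWEEN_SEGMENTS` if the position falls in no
segment; `CONFLICT` if any contradiction arose; `UNRESOLVED_ALL_HET` if no
homozygote seeded anything (including "no sequenced members at all"); else
`IMPUTED`. Sequenced individuals are themselves imputation targets, so their
missing calls are filled; their observed non-missing calls pass through
untouched except at conflicted loci. Status fractions are reported both over
(family, locus) cells and over loci (it is ambiguous which of the two a
published aggregate refers to; the per-locus roll-up uses the precedence
imputed > conflict > unresolved > between-segments across families).

## Label recovery for untyped members

For an untyped individual U, each labeled child's haplotype on the U side is
a haplotype U carries. Two distinct transmitted labels recover both of U's
haplotypes; one recovers exactly one; three or more is a hard transmission
error. Sweeps repeat until a fixed point so a recovered parent can anchor a
grandparent. Founders' own pairs are canonical — (self:1, self:2) — by
definition, so recovery is substantive only for untyped non-founders.
Recovered labels are oriented into the paternal/maternal slots via the
parents' known pairs when possible, otherwise placed deterministically in
sorted order; transmission checks compare a child's label against the
parent's pair as a set, so an unorientable placement cannot create false
violations. Recovery is monotone (never removes or changes a known label)
and idempotent at its fixed point.

## Chip/sequence concordance and reconciliation

Markers are matched by (chromosome, position) with allele-pair verification
allowing reverse complement; unambiguous strand flips are normalised to the
chip strand *before* comparison (whether to normalise first or merely
exclude ambiguous pairs is a documented choice, configurable via
`normalize_strand`). A/T and C/G SNPs are self-complementary, so their
called-vs-called discordances are excluded from the mismatch class only —
missingness classification is unaffected because strand encoding cannot
masquerade as a missing call. The three inconsistency categories partition
the inconsistent cells exactly. Reconciliation gives the chip call priority
wherever both platforms report or the sequence call is missing; it is
idempotent and leaves zero mismatches on the shared set. Families without
sequenced members are excluded from the report.

## Recombination breakpoints

A label switch between consecutive segments on one side of a meiosis is a
crossover; the reported interval is the open gap between the last
informative marker of the left segment and the first of the right, and its
length is the resolution. A child's label sequence also changes where it
copies straight through its parent's own breakpoint; when the parent's
labels are known on both flanks, a switch that follows a single parental
slot through the parent's simultaneous switch is suppressed, attributing
each crossover to exactly one meiosis (naive per-individual switch counting
would recount ancestral crossovers in every descendant). With parent-phased
labels every detected switch has a structurally determined side; the
`unknown` side value exists in the data model for unphasable inputs and its
count is carried through the resolution summary. Double crossovers inside
one segment — or an even number inside one inter-marker gap — are invisible
to any label-based method; this is a documented limitation, not a detection
failure.

## The simulator: what it emulates and what it does not

The generator mirrors the structure of a chip+sequence family study on one
chromosome: a regular multi-generation family (default three generations,
one founder couple, three children per couple, every non-final-generation
child marrying a new founder spouse → 17 members), ~70% of members
chip-typed and ~48% of the typed members sequenced (the nested-design ratios
of such studies), a 200-Mb / 2.2-Morgan chromosome, per-marker alternate
allele frequencies uniform on (0.1, 0.9) by default (a Beta sampler is
available), 2% sequence and 0.7% chip missingness, and a 0.5% genotype error
rate. Errors replace a call with a uniformly random *different* genotype —
the genotype-level miscall model appropriate for conflict analysis — and
missingness is independent per call. Crossovers are Poisson with no
interference; interference is irrelevant to the algorithms under test.
Chip markers are a random subset of sequence marker positions.

Simulated truth provides: per-individual haplotype allele and label arrays,
the family segment partition derived from all label-visible crossovers, a
transmission-consistent truth labeling, and truth crossover records.
`truth_crossovers` lists the *label-visible* events: even numbers of
crossovers in one inter-marker gap cancel (the odd-parity representative
position is kept) and crossovers outside the marker span are excluded; raw
draws are retained separately. All randomness flows from one seeded
`numpy` generator, so equal configs give byte-identical output files.

What the simulator does **not** emulate: linkage disequilibrium among
founder haplotypes, demographic structure, platform-specific error profiles
(e.g. depth-dependent miscalls, reference bias), Mendelian-consistent error
correlation within families, or read-level artifacts. Passing tests
therefore demonstrate the correctness of the bookkeeping and inference on
the stated model, not robustness to real-data error structure; in
particular, real sequence errors are not independent across sites, so real
conflict counts will deviate from the simulated proportionality.

## Numerical and design choices

- Coordinates are 1-based base pairs throughout; segments use inclusive
  bounds; breakpoint intervals are open.
- Genotypes are unordered allele pairs; imputed genotypes are ordered
  (paternal, maternal) internally, with provenance, and compared as
  multisets.
- Accuracy = correctly imputed alleles / imputed alleles, under best
  unordered-pair matching; single-allele genotypes contribute their one
  allele, correct if present in the truth pair; loci with missing truth are
  skipped; zero imputed alleles ⇒ accuracy undefined (reported as such).
- Individual ids must be globally unique (VCF sample columns are flat).
- Default thresholds: 5% maximum per-marker missing rate before imputation;
  20-kb resolution threshold in breakpoint summaries.
- Deterministic iteration (sorted ids) everywhere; the CLI writes its
  resolved configuration next to its outputs; identical inputs give
  byte-identical outputs.

## Problem sizes used in validation

The bundled studies use desk-scale sizes chosen to make every check exact
and fast: the nine-member worked example (2 variants); a 17-member
three-generation family with 2,000 sequence loci and 8 sequenced members
(5 founders + 3 children, guaranteeing every founder haplotype is sequenced)
for masked-accuracy recovery; 600-locus replicates across error rates
{0, 0.5%, 1%, 2%} for conflict-rate monotonicity; 200 meioses at 2.2 Morgans
with 1,000 markers for breakpoint containment; and 1,000 random ≤12-label
per-locus systems against the exhaustive-enumeration oracle.

## Known limitations

- No population-level linkage-disequilibrium imputation; unresolved labels
  stay unresolved rather than being guessed from allele frequencies.
- No probabilistic or dosage output; no genotype-likelihood input.
- Mendelian-consistent genotype errors that do not produce label conflicts
  are undetectable by construction.
- The inference is unit propagation only (see above); loci resolvable only
  by global constraint reasoning are left partially resolved.
- Sex-chromosome inheritance, pedigree drawing and affection-status handling
  are out of scope.
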