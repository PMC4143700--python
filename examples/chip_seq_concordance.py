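"""Audit sequence calls against chip calls and reconcile the two.

Simulates a dataset with genotype errors and missingness on both platforms,
classifies every shared (individual, marker) cell, and then reconciles:
where the platforms disagree the chip call wins, after which no mismatches
remain.
"""

import pedimpute as pi
from pedimpute.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    n_seq_markers=1500, n_chip_markers=400, seed=11,
    genotype_error_rate=0.01, missing_rate_chip=0.007, missing_rate_seq=0.02,
    fraction_typed=1.0, fraction_sequenced_of_typed=0.5,
)
ds = simulate_dataset(cfg)
report = pi.compare_chip_sequence(ds.observed_chip, ds.observed_seq, ds.pedigree)
o = report.overall

print(f"shared markers: {report.n_shared_markers}; cells compared: {o.n_cells}")
print(f"inconsistent: {o.n_inconsistent} ({100 * o.n_inconsistent / o.n_cells:.2f}%)")
if o.n_inconsistent:
    print(f"  missing in chip data:     {100 * o.missing_in_gwas / o.n_inconsistent:.1f}%")
    print(f"  missing in sequence data: {100 * o.missing_in_wgs / o.n_inconsistent:.1f}%")
    print(f"  genuine mismatches:       {100 * o.mismatch / o.n_inconsistent:.1f}%")
print(f"strand-ambiguous (A/T, C/G) discordances excluded: {o.strand_ambiguous_excluded}")

reconciled = pi.reconcile_genotypes(ds.observed_chip, ds.observed_seq)
after = pi.compare_chip_sequence(ds.observed_chip, reconciled, ds.pedigree).overall
print(f"mismatches after chip-wins reconciliation: {after.mismatch}")
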