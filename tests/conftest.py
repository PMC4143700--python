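"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates every assignment of alleles {1, 2} to the haplotype
labels of one locus and keeps those satisfying all sequenced-member
constraints (a homozygote fixes its known labels; a heterozygote's two known
labels must differ).  It is used to check that unit propagation is sound:
every propagated allele holds in all satisfying assignments, and every
reported conflict implies an unsatisfiable system.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pedimpute import MISSING, Label
from pedimpute.demo import example_dataset
from pedimpute.simulate import SimulationConfig, simulate_dataset


def enumerate_satisfying(labels, members):
    """All satisfying allele assignments, as a (n_solutions, n_labels) array.

    ``members`` are (individual_id, (label_or_None, label_or_None), (a, b))
    with unordered genotype alleles in {0, 1, 2}.
    """
    labels = list(labels)
    idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    grid = np.array(list(itertools.product((1, 2), repeat=k)), dtype=np.int8)
    mask = np.ones(len(grid), dtype=bool)
    for _iid, (l1, l2), (a, b) in members:
        if a == MISSING:
            continue
        if a == b:  # homozygote: every known label carries a
            for l in (l1, l2):
                if l is not None:
                    mask &= grid[:, idx[l]] == a
        else:  # heterozygote: two known labels take the two alleles
            if l1 is not None and l2 is not None:
                if l1 == l2:
                    mask &= False
                else:
                    mask &= grid[:, idx[l1]] != grid[:, idx[l2]]
    return labels, grid[mask]


def random_locus_instance(rng, max_labels=12, max_members=10):
    """A random per-locus constraint system for the oracle comparison."""
    n_labels = int(rng.integers(2, max_labels + 1))
    labels = [Label("F", f"f{i}", 1 + (i % 2)) for i in range(n_labels)]
    n_members = int(rng.integers(1, max_members + 1))
    genotypes = [(1, 1), (2, 2), (1, 2), (0, 0)]
    members = []
    for m in range(n_members):
        pair = []
        for _ in range(2):
            if rng.random() < 0.1:
                pair.append(None)
            else:
                pair.append(labels[int(rng.integers(n_labels))])
        gt = genotypes[int(rng.choice(4, p=[0.3, 0.3, 0.3, 0.1]))]
        members.append((f"m{m}", (pair[0], pair[1]), gt))
    return labels, members


@pytest.fixture
def demo_data():
    return example_dataset()


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noiseless three-generation dataset, everyone typed."""
    cfg = SimulationConfig(
        n_seq_markers=400,
        n_chip_markers=80,
        seed=7,
        genotype_error_rate=0.0,
        missing_rate_chip=0.0,
        missing_rate_seq=0.0,
        fraction_typed=1.0,
        fraction_sequenced_of_typed=0.5,
    )
    return simulate_dataset(cfg)
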