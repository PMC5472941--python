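"""Shared fixtures: small deterministic panels and expensive session-scoped
simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from popgenkit.genotype_io import (
    GenotypePanel,
    PopulationMap,
    Variant,
)
from popgenkit import synthetic_data as sd


def make_panel(genotypes, samples=None, chrom="1", pos_step=10_000, ancestral_ref=True):
    """GenotypePanel from a (variants x samples) array of 0/1/2/-1 codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_smp = g.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_smp)]
    variants = [
        Variant(chrom, (i + 1) * pos_step, None, "A", "G", "A" if ancestral_ref else None)
        for i in range(n_var)
    ]
    return GenotypePanel(
        variants=variants,
        samples=list(samples),
        genotypes=g,
        counted=np.array(["alt"] * n_var, dtype=object),
    )


@pytest.fixture
def tiny_panel():
    return make_panel([[0, 1, 2], [2, 2, 0], [1, 0, 1]])


@pytest.fixture
def popmap_two():
    return PopulationMap(
        {"s0": "popA", "s1": "popA", "s2": "popB"},
        {"popA": "G1", "popB": "G2"},
    )


@pytest.fixture(scope="session")
def sweep_pair():
    """Matched (sweep, neutral) haplotype panels; shared across scan tests."""
    return sd.simulate_sweep_pair(seed=1)


@pytest.fixture(scope="session")
def neutral_hap_panel():
    """Equilibrium neutral haplotype panel for iHS calibration checks."""
    return sd.coalescent_diploid_panel(
        100, 5000, sequence_length=1.5e6, recomb_rate=1e-7, seed=11
    )
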