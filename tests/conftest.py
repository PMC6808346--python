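import numpy as np
import pandas as pd
import pytest

from polyprofile.synthetic_cohort import (
    GeneBlock,
    Instrument,
    SimulationConfig,
    TraitArchitecture,
    simulate_genotypes,
)


def make_sim_config(n=300, blocks=((60, 0.7),), freq=(0.1, 0.5),
                    missing_rate=0.0, seed=11, architectures=()):
    gene_blocks = [
        GeneBlock(f"GENE{i}", m, rho, chrom=str(i + 1), start=1_000_000,
                  end=1_000_000 + 1000 * m)
        for i, (m, rho) in enumerate(blocks)
    ]
    return SimulationConfig(
        n_individuals=n, gene_blocks=gene_blocks, allele_freq_range=freq,
        architectures=list(architectures), missing_rate=missing_rate, seed=seed,
    )


def make_architecture(n_snps, k=5, h2=0.3, seed=3, name="trait",
                      bounds=(0.0, 100.0), integer=False, env_loading=0.0):
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_snps, size=k, replace=False))
    return TraitArchitecture(
        name=name, causal_snp_indices=idx, effect_sizes=rng.standard_normal(k),
        h2=h2, instrument=Instrument(*bounds, integer=integer),
        env_loading=env_loading,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """300 individuals x 3 LD blocks (60 SNPs), 2% missingness."""
    cfg = make_sim_config(n=300, blocks=((20, 0.7), (25, 0.0), (15, 0.9)),
                          missing_rate=0.02, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """500 individuals x 40 SNPs, no missingness (for exact checks)."""
    cfg = make_sim_config(n=500, blocks=((40, 0.5),), missing_rate=0.0, seed=7)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
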