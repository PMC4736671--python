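import numpy as np
import pytest

from domgblup import (
    SimConfig,
    build_additive_grm,
    build_dominance_grm,
    estimate_allele_frequencies,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small half-sib dataset reused across modules: 5 sires x 6 daughters,
    80 SNPs, 2 records per animal."""
    cfg = SimConfig(
        n_sires=5, daughters_per_sire=6, n_snps=80, records_per_animal=2, seed=11
    )
    genotypes, truth, records = simulate_dataset(cfg)
    return cfg, genotypes, truth, records


@pytest.fixture(scope="session")
def small_grms(small_dataset):
    _, genotypes, _, _ = small_dataset
    freqs = estimate_allele_frequencies(genotypes)
    return freqs, build_additive_grm(genotypes, freqs), build_dominance_grm(genotypes, freqs)


@pytest.fixture(scope="session")
def medium_dataset():
    """Larger dataset for recovery-direction checks: 10 sires x 30 daughters."""
    cfg = SimConfig(
        n_sires=15, daughters_per_sire=20, n_snps=500, records_per_animal=2, seed=23
    )
    genotypes, truth, records = simulate_dataset(cfg)
    return cfg, genotypes, truth, records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
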