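import numpy as np
import pytest

from qrfcca import (
    SimulationDesign,
    build_haplotype_pool,
    sample_genotype_block,
)


@pytest.fixture(scope="session")
def small_design():
    """A 20-SNP gene design with strong local LD, used across modules."""
    return SimulationDesign(
        n_snps=20,
        n_rare=5,
        n_common=15,
        ld_rho=0.8,
        n_haplotypes=4000,
        n_traits=5,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_pool(small_design):
    return build_haplotype_pool(small_design, np.random.default_rng(3))


@pytest.fixture(scope="session")
def small_block(small_pool):
    """A 50-sample draw from the small pool (50 x ~20 dosage matrix)."""
    return sample_genotype_block(small_pool, 50, np.random.default_rng(4))


@pytest.fixture(scope="session")
def gene_design():
    """The full-scale gene: 1,000 SNPs (600 rare, 400 common), AR(1) LD."""
    return SimulationDesign(n_traits=15, correlation_regime="high", seed=7)


@pytest.fixture(scope="session")
def gene_pool(gene_design):
    return build_haplotype_pool(
        gene_design,
        np.random.default_rng(np.random.SeedSequence(entropy=7, spawn_key=(0,))),
    )
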