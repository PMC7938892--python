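import numpy as np
import pytest

from fsstab import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_sim():
    """A small complete simulated dataset shared across tests."""
    cfg = SimConfig(
        n_samples=400,
        n_snps=100,
        n_qtl=8,
        h2=0.6,
        ld_rho=0.0,
        ld_block_size=1,
        n_farmbatch=4,
        missing_rate=0.0,
        seed=11,
    )
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
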