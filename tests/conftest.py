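import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import episcore as ep


@pytest.fixture(scope="session")
def small_dataset():
    """600 samples x 30 SNPs with 3% missingness and no planted effects."""
    cfg = ep.SimulationConfig(n_samples=600, n_snps=30, seed=7, missing_rate=0.03)
    geno, pheno = ep.simulate_dataset(cfg)
    return geno, pheno


@pytest.fixture(scope="session")
def planted_dataset():
    """4000 samples x 60 SNPs with one allele-product interaction planted."""
    rng = np.random.default_rng(42)
    mafs = rng.uniform(0.1, 0.5, 60)
    mafs[10] = mafs[20] = 0.35
    table = ep.product_penetrance(0.3, 0.6)
    cfg = ep.SimulationConfig(
        n_samples=4000, n_snps=60, mafs=tuple(mafs),
        planted_pairs=((10, 20, table),), seed=11,
    )
    return ep.simulate_dataset(cfg) + (10, 20)


def random_joint_tables(n_tables: int, seed: int, low: int = 3, high: int = 50):
    """Random 3x3x2 tables with all cells in [low, high]."""
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=(n_tables, 3, 3, 2))
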