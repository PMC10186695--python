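import numpy as np
import pandas as pd
import pytest

import chromoscale.contact as cc
from chromoscale.genome import BinnedGenome
from chromoscale.synthetic import ArchitectureConfig, simulate_study


@pytest.fixture(scope="session")
def small_grid():
    return BinnedGenome({"chr1": 100_000, "chr2": 60_000}, 5_000)


@pytest.fixture(scope="session")
def small_config():
    """Tiny two-chromosome configuration for fast unit tests."""
    return ArchitectureConfig(
        chrom_sizes={"chr1": 1_500_000, "chr2": 1_000_000},
        depth=500_000, n_loops=6, compartment_block_mean=40,
        genes_per_mb=80, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, return_pairs=True)


@pytest.fixture(scope="session")
def study():
    """The benchmark-scale paired-condition dataset (10 Mb, depth 5e6)."""
    return simulate_study(ArchitectureConfig(seed=1), return_pairs=True)


@pytest.fixture(scope="session")
def depth_pair(study):
    return cc.depth_normalize(study.matrix_1, study.matrix_2)


@pytest.fixture(scope="session")
def balanced_5kb(depth_pair):
    d1, _ = depth_pair
    masked = cc.mask_low_coverage(d1)
    return masked, cc.kr_balance(masked)


@pytest.fixture(scope="session")
def random_symmetric():
    """Random dense symmetric nonnegative matrix wrapped as ContactMatrix."""
    rng = np.random.default_rng(3)
    n = 80
    grid = BinnedGenome({"chr1": n * 5_000}, 5_000)
    m = rng.gamma(2.0, 1.0, size=(n, n)) + 0.05
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return cc.ContactMatrix(grid, {"chr1": m})
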