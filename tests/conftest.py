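import numpy as np
import pytest

from ebbase import SimScenario, simulate_batch


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def homogeneous_batch():
    """10-replicate batch at iQCC=2 (Q=4), shared across model tests."""
    return simulate_batch(SimScenario(n_genes=2000, n_replicates=10, iqcc_true=2.0, seed=11))


@pytest.fixture(scope="session")
def binomial_batch():
    """10-replicate batch with no overdispersion (iQCC=1)."""
    return simulate_batch(SimScenario(n_genes=2000, n_replicates=10, iqcc_true=1.0, seed=12))


@pytest.fixture(scope="session")
def small_table():
    """Tiny deterministic table for I/O and arithmetic tests."""
    from ebbase import CountsTable

    return CountsTable.from_arrays(
        gene_ids=["g1", "g2", "g3"],
        samples=["s1", "s2", "s3"],
        m=[[3, 5, 2], [10, 0, 4], [30, 25, 28]],
        p=[[7, 5, 8], [0, 10, 6], [30, 35, 30]],
        chromosome=["1", "X", "2"],
    )
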