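import numpy as np
import pytest

from gwascoloc.synthetic import LdBlockSpec, simulate_genotypes


@pytest.fixture(scope="session")
def tight_block_panel():
    """Two well-separated high-LD blocks, 5000 samples (shared across tests)."""
    spec = LdBlockSpec(block_sizes=(10, 10), maf_range=(0.15, 0.5), rho=0.9)
    return simulate_genotypes(5000, spec, seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
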