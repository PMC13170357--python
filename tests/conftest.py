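import numpy as np
import pytest

from rbscreen import synthetic as syn


@pytest.fixture(scope="session")
def small_genome():
    """Two 50-kb chromosomes with 20 genes; shared across mapping tests."""
    spec = syn.SyntheticGenomeSpec(
        n_chromosomes=2, chromosome_lengths=(50_000, 50_000), n_genes=20,
        gene_length_range=(500, 2_000), seed=11,
    )
    return syn.simulate_genome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
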