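import pytest

from splintseq.oligo import synthetic_barcode_set
from splintseq.simulate import SimConfig, make_toy_pool, simulate_library


@pytest.fixture(scope="session")
def designs():
    return synthetic_barcode_set(8)


@pytest.fixture(scope="session")
def pool():
    return make_toy_pool()


@pytest.fixture(scope="session")
def clean_library(designs, pool):
    """Error-free library: 4 cells x 10 molecules x 5 duplicates."""
    config = SimConfig(
        seed=11, n_cells=4, molecules_per_cell=10, pcr_duplicates=5,
        substitution=0.0, insertion=0.0, deletion=0.0, truncation_prob=0.0,
    )
    reads, ledger = simulate_library(config, pool, designs)
    return reads, ledger, config


@pytest.fixture(scope="session")
def noisy_library(designs, pool):
    """Nanopore-like library: 5% substitutions, 1% insertions, 1% deletions."""
    config = SimConfig(
        seed=13, n_cells=4, molecules_per_cell=8, pcr_duplicates=5,
        substitution=0.05, insertion=0.01, deletion=0.01, truncation_prob=0.0,
    )
    reads, ledger = simulate_library(config, pool, designs)
    return reads, ledger, config
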