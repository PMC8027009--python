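import numpy as np
import pytest

from autozykit.simulate import SimConfig, simulate_dataset

# reduced study replicate for unit tests: same structure, minutes -> seconds
SMALL_CONFIG = SimConfig(
    seed=11,
    n_founder_haplotypes=80,
    burnin_generations=40,
    mutation_rate=8.0,
    n_chromosomes=4,
    chrom_length_bp=25_000_000,
    split_generations=15,
    heldout_pool_size=40,
    heldout_sample_haplotypes=40,
    pedigree_founders=20,
    pedigree_generations=4,
    generation_size=24,
    final_generation_size=30,
    array_target=1500,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
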