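import pytest

from apakit.pipeline import run_pipeline
from apakit.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_contigs=2, contig_length=120_000, n_genes=15,
                     n_rearranged_blocks=4, reads_per_sample=20_000,
                     samples_per_species=(3, 3), mispriming_rate=0.02,
                     species_specific_fraction=0.15, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline(small_dataset, cpm_min_samples=4)
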