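import numpy as np
import pytest

from ltbayes.sim import (ArchitectureConfig, DemographyConfig, GenomeConfig,
                         simulate_dataset)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete simulated replicate shared across tests."""
    genome = GenomeConfig(n_chromosomes=2, n_markers_per_chrom=100)
    demo = DemographyConfig(n_historical_generations=100)
    arch = ArchitectureConfig(n_qtl=20)
    return simulate_dataset(genome, demo, arch, seed=1)


@pytest.fixture(scope="session")
def tiny_training(tiny_dataset):
    return tiny_dataset.to_training_data()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
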