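import numpy as np
import pytest

from mitekit import synthdata as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=11, n_chromosomes=2, chrom_length=20_000,
                               copies_per_genome=6, copy_divergence=0.03,
                               tsd_decay_fraction=0.5)


@pytest.fixture(scope="session")
def small_ref(small_config):
    """A modest reference genome shared by read-only tests."""
    return sd.generate_reference(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
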