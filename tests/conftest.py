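import numpy as np
import pytest
from hypothesis import settings

from diazoscan import Catalog, SimulationConfig, generate_reference_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Three genera, short genes: cheap catalog for unit tests."""
    return SimulationConfig(
        n_genera=3,
        gene_lengths={"nifH": 450, "nifD": 600, "nifK": 660},
        n_reads=300,
        read_length=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config) -> Catalog:
    return generate_reference_catalog(small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
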