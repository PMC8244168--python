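import numpy as np
import pytest

from iccmap.graphs import make_lattice_graph
from iccmap.model import ModelSpec
from iccmap.simulate import (
    LinkageConfig,
    SimulationConfig,
    simulate_latent_fields,
    simulate_panel,
    simulate_registry,
)

SMALL_AGES = ("15-29", "30-44", "45-59", "60+")


@pytest.fixture(scope="session")
def lattice_4x4():
    return make_lattice_graph(4, 4)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_rows=4, n_cols=4, n_years=5, age_groups=SMALL_AGES, seed=7
    )


@pytest.fixture(scope="session")
def small_panel(lattice_4x4, small_config):
    fields = simulate_latent_fields(lattice_4x4, small_config)
    return simulate_panel(lattice_4x4, fields, small_config)


@pytest.fixture(scope="session")
def small_registry(small_panel):
    return simulate_registry(small_panel, LinkageConfig(seed=5, sentinel_n=2000))


@pytest.fixture(scope="session")
def full_spec():
    return ModelSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
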