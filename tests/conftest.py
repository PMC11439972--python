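import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_network():
    """Miniature column (same topology, ~5% size) shared across tests."""
    from barrelcircuit.fixtures import make_toy_network_fixture

    return make_toy_network_fixture(size_scale=0.05, seed=11)


@pytest.fixture(scope="session")
def population_table():
    from barrelcircuit.params import build_population_table

    return build_population_table()


@pytest.fixture(scope="session")
def probability_matrix():
    from barrelcircuit.connectivity import assemble_probability_matrix

    return assemble_probability_matrix()
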