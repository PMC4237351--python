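import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netnoise import NetworkGwas, SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One default-scale synthetic study (planted module, strong signal)."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(small_dataset):
    """The study fitted with a light permutation budget."""
    model = NetworkGwas.from_synthetic(small_dataset)
    return model.fit(n_perm=100, seed=5)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
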