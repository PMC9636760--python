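import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from chemotax import SyntheticSpec, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic dataset (4 groups x 10 compounds, 2 clades x 20 species)."""
    return generate_dataset(SyntheticSpec(seed=1))


@pytest.fixture()
def bowtie() -> nx.Graph:
    """Two triangles sharing a single hinge node H."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("A", "H"), ("B", "H"), ("C", "D"), ("C", "H"), ("D", "H")])
    return g


@pytest.fixture()
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g
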