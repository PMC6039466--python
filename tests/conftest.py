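import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def relabeled(g: nx.Graph, prefix: str = "N") -> nx.Graph:
    """Give integer-labelled toy graphs gene-symbol-like string labels."""
    return nx.relabel_nodes(g, {i: f"{prefix}{i}" for i in g.nodes()})


@pytest.fixture
def path_abc() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def star_1_3() -> nx.Graph:
    """Star: center C with leaves L1..L3."""
    g = nx.Graph()
    g.add_edges_from([("C", "L1"), ("C", "L2"), ("C", "L3")])
    return g


@pytest.fixture
def fused_stars() -> nx.Graph:
    """Two star centers X and Y joined by an edge, 4 leaves each."""
    g = nx.Graph()
    g.add_edge("X", "Y")
    for i in range(4):
        g.add_edge("X", f"XL{i}")
        g.add_edge("Y", f"YL{i}")
    return g


def random_simple_graph(n: int, m: int, seed: int) -> nx.Graph:
    """Deterministic random graph with string labels (no self-loops)."""
    m = min(m, n * (n - 1) // 2)
    return relabeled(nx.gnm_random_graph(n, m, seed=seed))
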