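import numpy as np
import pytest

from concept_cascade import ConceptSystem, Graph


def make_random_graph(n: int, p_edge: float, seed: int, directed: bool = False) -> Graph:
    """Erdős–Rényi style test graph."""
    rng = np.random.default_rng(seed)
    g = Graph(n, directed=directed)
    for u in range(n):
        targets = range(n) if directed else range(u + 1, n)
        for v in targets:
            if u != v and rng.random() < p_edge and not g.has_edge(u, v):
                g.add_edge(u, v)
    return g


@pytest.fixture
def path3_directed() -> Graph:
    """A -> B -> C (nodes 0, 1, 2)."""
    g = Graph(3, directed=True)
    g.add_edge(0, 1)
    g.add_edge(1, 2)
    return g


@pytest.fixture
def star10() -> Graph:
    """Hub 0 with leaves 1..10."""
    g = Graph(11)
    for leaf in range(1, 11):
        g.add_edge(0, leaf)
    return g


@pytest.fixture
def triangle_pendant() -> Graph:
    """Triangle 0-1-2 plus pendant node 3 attached to 0."""
    g = Graph(4)
    g.add_edge(0, 1)
    g.add_edge(1, 2)
    g.add_edge(0, 2)
    g.add_edge(0, 3)
    return g


@pytest.fixture
def clique5() -> Graph:
    g = Graph(5)
    for u in range(5):
        for v in range(u + 1, 5):
            g.add_edge(u, v)
    return g


@pytest.fixture
def icm_boost() -> ConceptSystem:
    return ConceptSystem(r=2.0, p=0.1, model_tag="ICM")


@pytest.fixture
def icm_inhibit() -> ConceptSystem:
    return ConceptSystem(r=0.0, p=0.1, model_tag="ICM")
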