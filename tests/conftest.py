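import networkx as nx
import pytest


@pytest.fixture
def two_triangles():
    """Two disjoint triangles; planted partition is the two triangles."""
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")])
    part = {n: (0 if n in "abc" else 1) for n in g}
    return g, part


@pytest.fixture
def bridged_triangles(two_triangles):
    """Two triangles joined by a single bridge edge."""
    g, part = two_triangles
    g = g.copy()
    g.add_edge("c", "d")
    return g, part


def random_planted_graph(rng, n_blocks=2, block_size=4, p_in=1.0, p_out=0.2):
    """Small planted graph (cliques by default, random inter-block edges)."""
    import itertools

    while True:
        g = nx.Graph()
        nodes = [f"v{i}" for i in range(n_blocks * block_size)]
        g.add_nodes_from(nodes)
        for u, v in itertools.combinations(range(len(nodes)), 2):
            same = u // block_size == v // block_size
            if rng.random() < (p_in if same else p_out):
                g.add_edge(nodes[u], nodes[v])
        if g.number_of_edges() and g.number_of_edges() < len(nodes) * (len(nodes) - 1) / 2:
            return g
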