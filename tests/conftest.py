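import networkx as nx
import numpy as np
import pytest

from statescape.mapper import ShapeGraph


def toy_graph(edges, label_counts, n_nodes=None):
    """Build a ShapeGraph directly from an edge list and per-node label counts.

    ``label_counts`` maps node -> {label: count}; member frame indices are
    assigned sequentially, which is all the measures need.
    """
    if n_nodes is None:
        n_nodes = max(
            [max(e) for e in edges] + list(label_counts), default=-1
        ) + 1
    g = nx.Graph()
    frame = 0
    for v in range(n_nodes):
        counts = {k: int(c) for k, c in label_counts.get(v, {}).items()}
        size = max(sum(counts.values()), 1)
        members = tuple(range(frame, frame + size))
        frame += size
        g.add_node(v, members=members, size=size, label_counts=counts)
    g.add_edges_from(edges)
    return ShapeGraph(graph=g, n_frames=frame)


@pytest.fixture
def path3():
    """3-node path A-B-C with one distinct label per node."""
    return toy_graph(
        [(0, 1), (1, 2)],
        {0: {"A": 1}, 1: {"B": 1}, 2: {"C": 1}},
    )


@pytest.fixture
def cycle4():
    return toy_graph(
        [(0, 1), (1, 2), (2, 3), (3, 0)],
        {v: {"L": 1} for v in range(4)},
    )


def random_connected_graph(rng: np.random.Generator, n_nodes: int) -> nx.Graph:
    """Random connected graph: a random spanning tree plus random extra edges."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        g.add_edge(int(order[i]), int(order[rng.integers(0, i)]))
    n_extra = int(rng.integers(0, n_nodes))
    for _ in range(n_extra):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    return g


def graph_with_uniform_labels(g: nx.Graph) -> ShapeGraph:
    """Wrap an nx graph as a ShapeGraph with one 'L'-frame per node."""
    return toy_graph(list(g.edges), {v: {"L": 1} for v in g.nodes},
                     n_nodes=g.number_of_nodes())
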