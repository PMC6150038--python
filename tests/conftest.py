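import itertools

import networkx as nx
import numpy as np
import pytest

import netcanon as nc
from netcanon.fixtures import petersen, petersen_ids


@pytest.fixture(scope="session")
def petersen_graph():
    return petersen()


@pytest.fixture(scope="session")
def petersen_dt(petersen_graph):
    return nc.all_pairs_distances(petersen_graph)


@pytest.fixture(scope="session")
def petersen_basis():
    """The metric basis (A, D, I) as vertex ids, in that order."""
    return petersen_ids("A", "D", "I")


def to_networkx(g: nc.Graph):
    G = nx.DiGraph() if g.directed else nx.Graph()
    G.add_nodes_from(range(g.n))
    G.add_edges_from(g.edges)
    return G


def random_graph(n: int, density: float, directed: bool, seed: int) -> nc.Graph:
    rng = np.random.default_rng(seed)
    if directed:
        pairs = [(u, v) for u in range(n) for v in range(n)
                 if u != v and rng.random() < density]
    else:
        pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
                 if rng.random() < density]
    return nc.build_graph(pairs, n, directed)


def random_relabel(g: nc.Graph, seed: int) -> nc.Graph:
    perm = np.random.default_rng(seed).permutation(g.n).tolist()
    return g.relabel(perm)


def all_undirected_graphs(n: int):
    """Every labeled simple undirected graph on n vertices."""
    slots = list(itertools.combinations(range(n), 2))
    for mask in range(1 << len(slots)):
        pairs = [p for i, p in enumerate(slots) if mask >> i & 1]
        yield nc.build_graph(pairs, n, directed=False)


def brute_force_class_key(g: nc.Graph) -> bytes:
    """Independent canonical key: min adjacency bytes over all n! orders."""
    a = g.adjacency
    return min(a[np.ix_(p, p)].tobytes()
               for p in map(list, itertools.permutations(range(g.n))))
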