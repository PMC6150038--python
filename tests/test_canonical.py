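import itertools

import networkx as nx
import numpy as np
import pytest

import netcanon as nc
from netcanon.canonical import (
    CanonizationError,
    adjacency_under_order,
    matrix_label,
    order_vertices,
    parse_label,
)
from netcanon.fixtures import complete, path, petersen_ids, star

from conftest import (
    all_undirected_graphs,
    brute_force_class_key,
    random_graph,
    random_relabel,
    to_networkx,
)


class TestOrderVertices:
    def test_petersen_basis_sorts_a_before_b(self, petersen_graph, petersen_dt,
                                             petersen_basis):
        pp = nc.parity_partition(petersen_graph)
        perm = order_vertices(petersen_dt, petersen_basis, pp, False)
        a, b = petersen_ids("A", "B")
        assert perm.index(a) < perm.index(b)
        assert perm[0] == a  # r(A|W) = (0, 2, 2) is the unique zero-leading rep

    def test_single_vertex_empty_basis(self):
        g = nc.build_graph([], 1, directed=False)
        perm = order_vertices(nc.all_pairs_distances(g), (),
                              nc.parity_partition(g), False)
        assert perm == (0,)

    def test_one_class_graph_falls_back_to_id_order(self):
        g = complete(3)
        perm = order_vertices(nc.all_pairs_distances(g), (),
                              nc.parity_partition(g), False)
        assert perm == (0, 1, 2)

    def test_non_resolving_basis_raises(self, petersen_graph, petersen_dt):
        pp = nc.parity_partition(petersen_graph)
        with pytest.raises(CanonizationError):
            order_vertices(petersen_dt, (0, 1), pp, False)


class TestAdjacencyUnderOrder:
    def test_directed_edge_follows_permutation(self):
        g = nc.build_graph([(0, 1)], 2, directed=True)
        assert adjacency_under_order(g, (0, 1)).tolist() == [[0, 1], [0, 0]]
        assert adjacency_under_order(g, (1, 0)).tolist() == [[0, 0], [1, 0]]

    def test_undirected_matrix_symmetric(self):
        g = random_graph(8, 0.4, directed=False, seed=1)
        m = adjacency_under_order(g, tuple(np.random.default_rng(0).permutation(8)))
        assert np.array_equal(m, m.T)

    def test_rejects_non_bijection(self):
        g = complete(3)
        with pytest.raises(ValueError):
            adjacency_under_order(g, (0, 0, 1))


@pytest.mark.parametrize("seed", range(10))
def test_parity_swap_leaves_matrix_unchanged(seed):
    """Transposing a twin pair in a random ordering never changes the
    permuted adjacency matrix."""
    rng = np.random.default_rng(seed)
    directed = seed % 2 == 0
    # Graphs with planted twins: duplicate a vertex's neighborhoods.
    g = random_graph(8, 0.4, directed, seed)
    pairs = [(u, v) for u, v in g.edges]
    extra = [(8 if u == 0 else u, 8 if v == 0 else v)
             for u, v in g.edges if 0 in (u, v)]
    g = nc.build_graph(pairs + extra, 9, directed)
    twins = [(u, v) for u, v in itertools.combinations(range(9), 2)
             if nc.are_parity(g, u, v)]
    assert twins, "construction must plant at least one twin pair"
    perm = list(rng.permutation(9))
    m0 = adjacency_under_order(g, perm)
    for u, v in twins:
        swapped = perm.copy()
        i, j = swapped.index(u), swapped.index(v)
        swapped[i], swapped[j] = swapped[j], swapped[i]
        assert np.array_equal(adjacency_under_order(g, swapped), m0)


class TestCanonicalLabel:
    def test_label_round_trips_through_parser(self, petersen_graph):
        form = nc.canonical_label(petersen_graph)
        n, directed, m = parse_label(form.label)
        assert (n, directed) == (10, False)
        assert np.array_equal(m, form.matrix)
        assert np.array_equal(form.matrix,
                              adjacency_under_order(petersen_graph, form.ordering))

    def test_relabeled_petersen_same_label(self, petersen_graph):
        base = nc.canonical_label(petersen_graph).label
        for seed in range(10):
            assert nc.canonical_label(random_relabel(petersen_graph, seed)).label == base

    def test_one_edge_difference_changes_label(self):
        g1 = complete(4)
        g2 = nc.build_graph(sorted(g1.edges)[:-1], 4, directed=False)
        assert nc.canonical_label(g1).label != nc.canonical_label(g2).label

    def test_representative_choice_does_not_matter(self):
        for g in (star(5), complete(4),
                  random_graph(8, 0.5, directed=True, seed=7)):
            lo = nc.canonical_label(g, representative="min").label
            hi = nc.canonical_label(g, representative="max").label
            assert lo == hi

    def test_directed_path_vs_converging_pair(self):
        chain = nc.build_graph([(0, 1), (1, 2)], 3, directed=True)
        fork = nc.build_graph([(0, 1), (2, 1)], 3, directed=True)
        assert nc.canonical_label(chain).label != nc.canonical_label(fork).label
        assert not nc.is_isomorphic(chain, fork)


class TestIsIsomorphic:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_relabeled_copy(self, seed):
        g = random_graph(9, 0.3, directed=(seed % 2 == 0), seed=seed)
        assert nc.is_isomorphic(g, random_relabel(g, seed + 1))

    def test_degree_sequence_fast_path(self):
        assert not nc.is_isomorphic(path(4), star(3))

    def test_four_vertex_census_matches_vf2(self):
        """All pairs across the 11 undirected 4-vertex classes agree with
        a VF2 oracle."""
        reps = {}
        for g in all_undirected_graphs(4):
            reps.setdefault(brute_force_class_key(g), g)
        assert len(reps) == 11
        reps = list(reps.values())
        for g1, g2 in itertools.combinations(reps, 2):
            assert not nc.is_isomorphic(g1, g2)
            assert not nx.is_isomorphic(to_networkx(g1), to_networkx(g2))


def test_labels_separate_exactly_the_isomorphism_classes_n4():
    """On all 64 labeled 4-vertex graphs, equal label <=> equal brute-force
    canonical key (min over all 4! permutations)."""
    by_key = {}
    for g in all_undirected_graphs(4):
        by_key.setdefault(brute_force_class_key(g), set()).add(
            nc.canonical_label(g).label)
    labels = [next(iter(s)) for s in by_key.values()]
    assert all(len(s) == 1 for s in by_key.values())
    assert len(set(labels)) == len(by_key)
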