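import itertools

import networkx as nx
import pytest

import netcanon as nc
from netcanon.fixtures import complete, path, petersen_ids, star

from conftest import random_graph, random_relabel, to_networkx


class TestMetricRepresentation:
    def test_petersen_printed_representations(self, petersen_dt, petersen_basis):
        b, e, c = petersen_ids("B", "E", "C")
        rep = lambda v: nc.metric_representation(petersen_dt, v, petersen_basis, False)
        assert rep(b) == (1, 2, 2)
        assert rep(e) == (1, 1, 2)
        assert rep(c) == (2, 1, 1)

    def test_basis_member_coordinate_is_zero(self, petersen_dt, petersen_basis):
        for j, w in enumerate(petersen_basis):
            assert nc.metric_representation(petersen_dt, w, petersen_basis, False)[j] == 0

    def test_directed_entries_are_distance_pairs(self):
        g = nc.build_graph([(0, 1), (1, 2)], 3, directed=True)
        dt = nc.all_pairs_distances(g)
        assert nc.metric_representation(dt, 2, (0,), True) == ((3, 2),)


class TestIsResolving:
    def test_petersen_basis_resolves(self, petersen_dt, petersen_basis):
        assert nc.is_resolving(petersen_dt, petersen_basis, range(10), False)

    def test_no_two_subset_resolves_petersen(self, petersen_dt):
        for W in itertools.combinations(range(10), 2):
            assert not nc.is_resolving(petersen_dt, W, range(10), False)

    def test_single_target_resolved_by_empty_set(self, petersen_dt):
        assert nc.is_resolving(petersen_dt, (), [3], False)
        assert not nc.is_resolving(petersen_dt, (), [3, 4], False)


class TestMinimumResolvingSets:
    def test_petersen_dimension_three(self, petersen_graph, petersen_basis):
        res = nc.minimum_resolving_sets(petersen_graph)
        assert res.dimension == 3
        assert tuple(sorted(petersen_basis)) in res.bases

    @pytest.mark.parametrize("q", [3, 4, 5])
    def test_complete_graph_closed_form(self, q):
        assert nc.minimum_resolving_sets(complete(q)).dimension == q - 1

    def test_star_closed_form(self):
        assert nc.minimum_resolving_sets(star(4)).dimension == 3  # n=5 -> n-2

    def test_path_endpoints_are_the_only_bases(self):
        res = nc.minimum_resolving_sets(path(5))
        assert res.dimension == 1
        assert set(res.bases) == {(0,), (4,)}

    def test_work_cap_raises(self, petersen_graph):
        with pytest.raises(nc.SearchCapExceeded):
            nc.minimum_resolving_sets(petersen_graph, max_combinations=5)


class TestMinimumAdvancedResolvingSets:
    def test_complete_graph_dimension_zero(self):
        g = complete(6)
        res = nc.minimum_advanced_resolving_sets(g, nc.parity_partition(g))
        assert res.dimension == 0
        assert res.bases == ((),)

    def test_star_dimension_one_both_singletons(self):
        g = star(5)
        res = nc.minimum_advanced_resolving_sets(g, nc.parity_partition(g))
        assert res.dimension == 1
        assert set(res.bases) == {(0,), (1,)}

    def test_twin_free_graph_reduces_to_base_search(self, petersen_graph):
        pp = nc.parity_partition(petersen_graph)
        adv = nc.minimum_advanced_resolving_sets(petersen_graph, pp)
        base = nc.minimum_resolving_sets(petersen_graph)
        assert adv.dimension == base.dimension == 3
        assert set(adv.bases) == set(base.bases)


def _oracle_metric_dimension(g: nc.Graph):
    """Independent brute force: networkx BFS distances, every subset of
    every size, plain tuple comparison."""
    G = to_networkx(g)
    dist = {v: dict(nx.single_source_shortest_path_length(G, v))
            for v in range(g.n)}
    def d(u, v):
        return dist[u].get(v, g.n)
    def rep(v, W):
        if g.directed:
            return tuple((d(v, w), d(w, v)) for w in W)
        return tuple(d(v, w) for w in W)
    for s in range(0, g.n + 1):
        hits = [W for W in itertools.combinations(range(g.n), s)
                if len({rep(v, W) for v in range(g.n)}) == g.n]
        if hits:
            return s, set(hits)
    raise AssertionError


@pytest.mark.parametrize("seed", range(8))
def test_brute_force_oracle_agreement(seed):
    g = random_graph(seed % 3 + 5, 0.15 + 0.08 * seed, directed=(seed % 2 == 0),
                     seed=seed)
    res = nc.minimum_resolving_sets(g)
    dim, bases = _oracle_metric_dimension(g)
    assert res.dimension == dim
    assert set(res.bases) == bases


@pytest.mark.parametrize("seed", range(6))
def test_advanced_dimension_never_exceeds_metric_dimension(seed):
    g = random_graph(8, 0.3 + 0.05 * seed, directed=(seed % 2 == 0), seed=seed)
    mu = nc.minimum_resolving_sets(g).dimension
    nu = nc.minimum_advanced_resolving_sets(g, nc.parity_partition(g)).dimension
    assert nu <= mu


def test_every_ordering_of_a_resolving_set_resolves(petersen_graph, petersen_basis):
    dt = nc.all_pairs_distances(petersen_graph)
    for W in itertools.permutations(petersen_basis):
        assert nc.is_resolving(dt, W, range(10), False)


@pytest.mark.parametrize("seed", range(4))
def test_dimension_invariant_under_relabeling(seed):
    g = random_graph(7, 0.35, directed=(seed % 2 == 0), seed=seed)
    h = random_relabel(g, seed + 99)
    assert (nc.minimum_resolving_sets(g).dimension
            == nc.minimum_resolving_sets(h).dimension)
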