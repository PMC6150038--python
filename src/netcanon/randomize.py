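"""Degree-preserving null models by edge switching.

The move picks two distinct edges (a,b), (c,d) uniformly and rewires them to
(a,d), (c,b); it is rejected when it would create a self-loop or a duplicate
edge.  Directed swaps exchange heads only, so every vertex keeps its in- and
out-degree exactly; undirected swaps preserve plain degrees.  The switch
count targets successful swaps, with an attempt cap so rigid graphs (e.g. a
directed 3-cycle, where every candidate swap is rejected) still terminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, build_graph

#: Attempt cap = this factor times the requested number of successful swaps.
DEFAULT_ATTEMPT_FACTOR = 100


@dataclass(frozen=True)
class SwapStats:
    successful: int
    attempted: int
    capped: bool


@dataclass(frozen=True)
class Ensemble:
    """A reproducible collection of degree-preserving randomizations."""

    graphs: tuple
    n_switch_target: int
    seed: int
    swap_stats: tuple


def _switch_edges(edges: list, directed: bool, n_switches: int,
                  rng: np.random.Generator,
                  attempt_factor: int = DEFAULT_ATTEMPT_FACTOR) -> tuple:
    edge_set = set(edges)
    m = len(edges)
    successful = 0
    attempted = 0
    cap = attempt_factor * max(n_switches, 1)
    while successful < n_switches and attempted < cap:
        attempted += 1
        i = int(rng.integers(m))
        j = int(rng.integers(m))
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if not directed:
            # Both pairings of the four endpoints must be reachable; orient
            # each picked edge at random before the head exchange.
            if rng.integers(2):
                a, b = b, a
            if rng.integers(2):
                c, d = d, c
        e1, e2 = (a, d), (c, b)
        if a == d or c == b:
            continue
        if not directed:
            e1 = (min(e1), max(e1))
            e2 = (min(e2), max(e2))
        if e1 in edge_set or e2 in edge_set:
            continue
        old1 = edges[i] if directed else (min(edges[i]), max(edges[i]))
        old2 = edges[j] if directed else (min(edges[j]), max(edges[j]))
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        successful += 1
    return edges, SwapStats(successful=successful, attempted=attempted,
                            capped=successful < n_switches)


def edge_switch(g: Graph, n_switches: int, seed: int,
                attempt_factor: int = DEFAULT_ATTEMPT_FACTOR) -> Graph:
    """One randomization of ``g`` after ``n_switches`` successful swaps."""
    graph, _ = edge_switch_with_stats(g, n_switches, seed, attempt_factor)
    return graph


def edge_switch_with_stats(g: Graph, n_switches: int, seed: int,
                           attempt_factor: int = DEFAULT_ATTEMPT_FACTOR) -> tuple:
    """Like :func:`edge_switch` but also reports swap statistics."""
    if g.m < 2:
        raise ValueError("edge switching needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    edges, stats = _switch_edges(edges, g.directed, n_switches, rng,
                                 attempt_factor)
    return build_graph(edges, g.n, g.directed, labels=g.labels), stats


def build_ensemble(g: Graph, n_graphs: int, switch_factor: float = 10,
                   seed: int = 0,
                   attempt_factor: int = DEFAULT_ATTEMPT_FACTOR) -> Ensemble:
    """``n_graphs`` independent randomizations, each targeting
    ``switch_factor * |E|`` successful swaps; member ``i`` uses ``seed + i``."""
    n_switches = int(round(switch_factor * g.m))
    graphs = []
    stats = []
    for i in range(n_graphs):
        gi, si = edge_switch_with_stats(g, n_switches, seed + i, attempt_factor)
        graphs.append(gi)
        stats.append(si)
    return Ensemble(graphs=tuple(graphs), n_switch_target=n_switches,
                    seed=seed, swap_stats=tuple(stats))
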