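"""Simple directed / undirected graphs with dense integer vertex ids.

Vertices are always ``0..n-1``; string names, if any, live in the optional
``labels`` tuple and are otherwise ignored by every algorithm.  Graphs are
immutable: all derived structure (adjacency sets, the adjacency matrix) is
computed lazily and cached on the instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class GraphError(ValueError):
    """Invalid graph construction (self-loop, out-of-range endpoint, ...)."""


@dataclass(frozen=True)
class Graph:
    """A simple graph.

    Parameters
    ----------
    n : int
        Number of vertices; ids are ``0..n-1``.
    directed : bool
        Edge pairs are ordered if true, unordered (stored as ``(min, max)``)
        otherwise.
    edges : frozenset of (int, int)
        Edge set.  An antiparallel directed pair ``u->v``, ``v->u`` is two
        distinct edges; an undirected edge is a single ``(min, max)`` pair.
    labels : tuple of str, optional
        Display name per vertex id, used only at the I/O boundary.
    """

    n: int
    directed: bool
    edges: frozenset
    labels: tuple | None = None

    @property
    def m(self) -> int:
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        if self.directed:
            return (u, v) in self.edges
        return (min(u, v), max(u, v)) in self.edges

    @cached_property
    def adj_out(self) -> tuple:
        """Out-neighbor sets (plain neighbor sets when undirected)."""
        out = [set() for _ in range(self.n)]
        for u, v in self.edges:
            out[u].add(v)
            if not self.directed:
                out[v].add(u)
        return tuple(frozenset(s) for s in out)

    @cached_property
    def adj_in(self) -> tuple:
        if not self.directed:
            return self.adj_out
        inn = [set() for _ in range(self.n)]
        for u, v in self.edges:
            inn[v].add(u)
        return tuple(frozenset(s) for s in inn)

    @cached_property
    def adj_und(self) -> tuple:
        """Neighbor sets of the underlying undirected graph."""
        if not self.directed:
            return self.adj_out
        return tuple(frozenset(a | b) for a, b in zip(self.adj_out, self.adj_in))

    @cached_property
    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix, symmetric when undirected."""
        a = np.zeros((self.n, self.n), dtype=np.uint8)
        for u, v in self.edges:
            a[u, v] = 1
            if not self.directed:
                a[v, u] = 1
        return a

    def relabel(self, perm: Sequence[int]) -> "Graph":
        """Image of the graph under the map old id -> ``perm[old id]``."""
        pairs = [(perm[u], perm[v]) for u, v in self.edges]
        return build_graph(pairs, self.n, self.directed)


@dataclass(frozen=True)
class DistanceTable:
    """All-pairs shortest-path lengths with an unreachable sentinel.

    ``dist_out[u, v]`` is the number of edges on a shortest path from ``u``
    to ``v`` following edge direction; unreachable pairs hold ``sentinel``
    (fixed at ``n``, strictly above any finite distance).  ``dist_in`` is the
    transpose view, ``dist_in[u, v] = d(v, u)``.
    """

    dist_out: np.ndarray
    sentinel: int

    @property
    def dist_in(self) -> np.ndarray:
        return self.dist_out.T


def build_graph(edge_pairs: Iterable, n: int, directed: bool,
                labels: Sequence[str] | None = None) -> Graph:
    """Validate and construct a :class:`Graph`, deduplicating edges.

    Raises :class:`GraphError` naming the offending pair on a self-loop or
    an out-of-range endpoint.
    """
    if n < 0:
        raise GraphError(f"vertex count must be nonnegative, got {n}")
    edges = set()
    for pair in edge_pairs:
        u, v = pair
        if u == v:
            raise GraphError(f"self-loop ({u}, {v}) not allowed in a simple graph")
        if not (0 <= u < n and 0 <= v < n):
            raise GraphError(f"edge ({u}, {v}) has an endpoint outside [0, {n})")
        edges.add((u, v) if directed else (min(u, v), max(u, v)))
    lab = tuple(labels) if labels is not None else None
    if lab is not None and len(lab) != n:
        raise GraphError(f"expected {n} labels, got {len(lab)}")
    return Graph(n=n, directed=directed, edges=frozenset(edges), labels=lab)


def degrees(g: Graph, v: int) -> tuple:
    """``(in_degree, out_degree, total_degree)`` of ``v``.

    For undirected graphs all three equal the number of incident edges; for
    directed graphs total = in + out, so a mutual pair counts twice.
    """
    _check_vertex(g, v)
    din = len(g.adj_in[v])
    dout = len(g.adj_out[v])
    if not g.directed:
        return (din, din, din)
    return (din, dout, din + dout)


def neighborhoods(g: Graph, v: int) -> tuple:
    """``(N_in, N_out, N_total)`` as frozensets; all equal when undirected."""
    _check_vertex(g, v)
    return (g.adj_in[v], g.adj_out[v], g.adj_und[v])


def all_pairs_distances(g: Graph) -> DistanceTable:
    """BFS-exact all-pairs shortest paths; unreachable pairs get sentinel n."""
    if g.n == 0:
        return DistanceTable(np.zeros((0, 0), dtype=np.int64), 0)
    rows = [u for u, v in g.edges]
    cols = [v for u, v in g.edges]
    data = np.ones(len(rows), dtype=np.int8)
    sp = csr_matrix((data, (rows, cols)), shape=(g.n, g.n))
    d = shortest_path(sp, method="D", directed=g.directed, unweighted=True)
    d[np.isinf(d)] = g.n
    return DistanceTable(d.astype(np.int64), g.n)


def _check_vertex(g: Graph, v: int) -> None:
    if not (0 <= v < g.n):
        raise GraphError(f"vertex {v} outside [0, {g.n})")
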