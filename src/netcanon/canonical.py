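"""Canonical labeling from minimum advanced resolving sets.

The label of a graph is the lexicographic minimum, over every minimum
advanced resolving set and every ordering of it, of the adjacency matrix
under the vertex order that the ordered basis induces.  Two graphs are
isomorphic iff their labels are equal.

Vertex ordering.  An ordered basis W sorts the parity classes by the metric
representation of each class representative (coordinate-by-coordinate,
smaller distance earlier); class members are then listed contiguously in
ascending vertex id.  Sorting whole classes rather than individual vertices
matters: a twin of a basis vertex acquires a representation of its own that
can collide with a vertex from a different class, and breaking such a
cross-class tie by vertex id would not be isomorphism-invariant.  Ordering
by class keys never ties across classes (W resolves the representatives),
and the within-class order is immaterial because transposing a parity pair
leaves the permuted adjacency matrix bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import DistanceTable, Graph, all_pairs_distances
from .parity import ParityPartition, parity_partition
from .resolving import (
    DEFAULT_MAX_COMBINATIONS,
    metric_representation,
    minimum_advanced_resolving_sets,
)


class CanonizationError(RuntimeError):
    """Internal consistency failure while building a canonical form."""


@dataclass(frozen=True)
class CanonicalForm:
    """A canonical adjacency form.

    ``ordering[i]`` is the original vertex id placed at position ``i``;
    ``matrix`` is the adjacency of the graph with rows/columns permuted by
    ``ordering``; ``label`` serializes the matrix; ``basis`` is the ordered
    advanced resolving set achieving the lex-min.
    """

    ordering: tuple
    matrix: np.ndarray = field(compare=False)
    label: str
    basis: tuple


def order_vertices(dt: DistanceTable, W: Sequence[int], pp: ParityPartition,
                   directed: bool) -> tuple:
    """Total vertex order induced by the ordered basis ``W``.

    Parity classes are sorted by their representative's metric
    representation; ties across distinct classes signal that W was not an
    advanced resolving set and raise :class:`CanonizationError`.
    """
    keyed = []
    for idx, rep in enumerate(pp.representatives):
        key = metric_representation(dt, rep, W, directed)
        keyed.append((key, idx))
    keyed.sort()
    for (k1, _), (k2, c2) in zip(keyed, keyed[1:]):
        if k1 == k2:
            raise CanonizationError(
                f"representation collision across parity classes under W={tuple(W)}: "
                f"W does not resolve the representatives"
            )
    perm = []
    for _, idx in keyed:
        perm.extend(sorted(pp.classes[idx]))
    return tuple(perm)


def adjacency_under_order(g: Graph, perm: Sequence[int]) -> np.ndarray:
    """Adjacency matrix with ``matrix[i, j] = 1`` iff ``(perm[i], perm[j])``
    is an edge (unordered for undirected graphs)."""
    p = np.asarray(perm, dtype=np.intp)
    if sorted(perm) != list(range(g.n)):
        raise ValueError("perm must be a bijection on [0, n)")
    return g.adjacency[np.ix_(p, p)]


def matrix_label(matrix: np.ndarray, directed: bool) -> str:
    """Serialize ``n:<d|u>:<bits>`` — n^2 row-major bits when directed,
    the n(n-1)/2 upper-triangle row-major bits when undirected."""
    n = matrix.shape[0]
    if directed:
        bits = matrix.reshape(-1)
    else:
        bits = matrix[np.triu_indices(n, k=1)]
    return f"{n}:{'d' if directed else 'u'}:" + "".join("1" if b else "0" for b in bits)


def parse_label(label: str) -> tuple:
    """Decode a label back to ``(n, directed, matrix)``; exact inverse of
    :func:`matrix_label`."""
    ns, ds, bits = label.split(":")
    n = int(ns)
    directed = ds == "d"
    vals = np.fromiter((c == "1" for c in bits), dtype=np.uint8, count=len(bits))
    m = np.zeros((n, n), dtype=np.uint8)
    if directed:
        if len(vals) != n * n:
            raise ValueError("malformed directed label")
        m[:] = vals.reshape(n, n)
    else:
        iu = np.triu_indices(n, k=1)
        if len(vals) != len(iu[0]):
            raise ValueError("malformed undirected label")
        m[iu] = vals
        m += m.T
    return n, directed, m


def canonical_label(g: Graph, max_combinations: int = DEFAULT_MAX_COMBINATIONS,
                    representative: str = "min") -> CanonicalForm:
    """Canonical form of ``g`` via the four-step procedure.

    (1) partition vertices into parity classes; (2) find all minimum
    advanced resolving sets; (3) for every such basis and every ordering of
    it, permute the adjacency matrix by the induced vertex order; (4) keep
    the row-major lexicographic leader (0 sorts before 1).
    """
    pp = parity_partition(g, representative=representative)
    dt = all_pairs_distances(g)
    result = minimum_advanced_resolving_sets(g, pp, dt,
                                             max_combinations=max_combinations)
    best_key = None
    best_perm = None
    best_basis = None
    best_matrix = None
    adj = g.adjacency
    seen_perms = set()
    for base in result.bases:
        for ordered in itertools.permutations(base):
            perm = order_vertices(dt, ordered, pp, g.directed)
            if perm in seen_perms:
                continue
            seen_perms.add(perm)
            p = np.asarray(perm, dtype=np.intp)
            mat = adj[np.ix_(p, p)]
            key = mat.tobytes()
            if best_key is None or key < best_key:
                best_key, best_perm, best_basis, best_matrix = key, perm, ordered, mat
    return CanonicalForm(
        ordering=best_perm,
        matrix=best_matrix,
        label=matrix_label(best_matrix, g.directed),
        basis=tuple(best_basis),
    )


def is_isomorphic(g1: Graph, g2: Graph,
                  max_combinations: int = DEFAULT_MAX_COMBINATIONS) -> bool:
    """Isomorphism test: cheap invariants first, then canonical labels."""
    if g1.n != g2.n or g1.m != g2.m or g1.directed != g2.directed:
        return False
    if _degree_signature(g1) != _degree_signature(g2):
        return False
    pp1 = parity_partition(g1)
    pp2 = parity_partition(g2)
    if sorted(len(c) for c in pp1.classes) != sorted(len(c) for c in pp2.classes):
        return False
    l1 = canonical_label(g1, max_combinations=max_combinations)
    l2 = canonical_label(g2, max_combinations=max_combinations)
    return l1.label == l2.label


def _degree_signature(g: Graph) -> list:
    if g.directed:
        return sorted((len(g.adj_in[v]), len(g.adj_out[v])) for v in range(g.n))
    return sorted(len(g.adj_out[v]) for v in range(g.n))
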