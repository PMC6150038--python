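"""Exact enumeration of connected induced k-subgraphs (ESU) and the
canonical-label census.

ESU grows each subgraph from a root vertex, only ever extending with
neighbors whose id exceeds the root and that are not already adjacent to the
current subgraph, which yields every connected induced k-vertex subgraph
exactly once.  Connectivity for directed graphs is taken in the underlying
undirected sense (the usual motif-tool convention; feed-forward loops and
bi-fans are weakly connected patterns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

from .canonical import canonical_label
from .graph import Graph, build_graph

#: Guard against accidental huge enumerations; override via ``max_k``.
DEFAULT_MAX_K = 5

# Canonical labels of k-vertex induced subgraphs keyed by their raw
# adjacency bitmask under the sorted-vertex order; the mask is not an
# isomorphism invariant, but each mask maps deterministically to the label
# of the graph it encodes, so the cache is exact.
_label_cache: dict = {}


@dataclass(frozen=True)
class SubgraphCensus:
    """Occurrence counts of connected induced k-subgraphs per canonical label."""

    k: int
    counts: dict
    total: int

    def to_tsv(self) -> str:
        lines = ["label\tcount"]
        for label in sorted(self.counts):
            lines.append(f"{label}\t{self.counts[label]}")
        return "\n".join(lines) + "\n"


def enumerate_connected_subgraphs(g: Graph, k: int,
                                  max_k: int = DEFAULT_MAX_K) -> Iterator[tuple]:
    """Yield every connected induced k-vertex subgraph exactly once, as a
    sorted vertex tuple."""
    if not 1 <= k <= g.n:
        raise ValueError(f"k must be in [1, {g.n}], got {k}")
    if k > max_k:
        raise ValueError(f"k={k} exceeds the safety limit max_k={max_k}")
    adj = g.adj_und

    def extend(sub: list, ext: set, excluded: frozenset) -> Iterator[tuple]:
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_excluded = excluded | adj[w]
            new_ext = ext | {u for u in adj[w] if u > sub[0] and u not in excluded}
            sub.append(w)
            yield from extend(sub, new_ext, new_excluded)
            sub.pop()

    for root in range(g.n):
        if k == 1:
            yield (root,)
            continue
        ext0 = {u for u in adj[root] if u > root}
        yield from extend([root], ext0, frozenset({root}) | adj[root])


def induced_subgraph(g: Graph, vertices: tuple) -> Graph:
    """Induced subgraph on ``vertices`` (sorted), relabeled to ``0..k-1``
    preserving edge directions."""
    verts = sorted(vertices)
    index = {v: i for i, v in enumerate(verts)}
    pairs = []
    for i, u in enumerate(verts):
        for v in verts[i + 1:]:
            if g.directed:
                if (u, v) in g.edges:
                    pairs.append((index[u], index[v]))
                if (v, u) in g.edges:
                    pairs.append((index[v], index[u]))
            elif (u, v) in g.edges:
                pairs.append((index[u], index[v]))
    return build_graph(pairs, len(verts), g.directed)


def _subgraph_mask(g: Graph, verts: tuple) -> int:
    """Adjacency bitmask of the induced subgraph under sorted-vertex order."""
    verts = sorted(verts)
    mask = 0
    bit = 0
    k = len(verts)
    for i in range(k):
        u = verts[i]
        for j in range(i + 1, k):
            v = verts[j]
            if g.directed:
                if (u, v) in g.edges:
                    mask |= 1 << bit
                if (v, u) in g.edges:
                    mask |= 1 << (bit + 1)
                bit += 2
            else:
                if (u, v) in g.edges:
                    mask |= 1 << bit
                bit += 1
    return mask


def _label_from_mask(k: int, directed: bool, mask: int) -> str:
    key = (k, directed, mask)
    label = _label_cache.get(key)
    if label is None:
        pairs = []
        bit = 0
        for i in range(k):
            for j in range(i + 1, k):
                if directed:
                    if mask >> bit & 1:
                        pairs.append((i, j))
                    if mask >> (bit + 1) & 1:
                        pairs.append((j, i))
                    bit += 2
                else:
                    if mask >> bit & 1:
                        pairs.append((i, j))
                    bit += 1
        label = canonical_label(build_graph(pairs, k, directed)).label
        _label_cache[key] = label
    return label


def census(g: Graph, k: int, max_k: int = DEFAULT_MAX_K) -> SubgraphCensus:
    """Group all connected induced k-subgraphs by canonical label.

    Labels of repeated adjacency patterns are cached (there are at most
    ``2^(k(k-1))`` directed patterns), so the canonization cost is paid once
    per pattern, not once per occurrence.
    """
    counts: Counter = Counter()
    total = 0
    for verts in enumerate_connected_subgraphs(g, k, max_k=max_k):
        counts[_label_from_mask(k, g.directed, _subgraph_mask(g, verts))] += 1
        total += 1
    return SubgraphCensus(k=k, counts=dict(counts), total=total)
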