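"""Twin-vertex ("parity node") detection and the induced vertex partition.

Two vertices are parity nodes when their neighborhoods coincide outside the
pair itself — undirected: ``N(u) \\ {v} == N(v) \\ {u}``; directed: equal
in/out degrees and ``N+(u) \\ {v} == N+(v) \\ {u}``,
``N-(u) \\ {v} == N-(v) \\ {u}``.  The relation is an equivalence, and
transposing a parity pair in any vertex ordering leaves the (permuted)
adjacency matrix unchanged, which is what makes one-representative-per-class
canonization sound.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import Graph, _check_vertex


@dataclass(frozen=True)
class ParityPartition:
    """Equivalence classes of the parity relation.

    ``classes`` partition ``0..n-1``; ``representatives`` holds one designated
    vertex per class (aligned with ``classes``); ``class_of[v]`` is the index
    of v's class.
    """

    classes: tuple
    representatives: tuple
    class_of: tuple

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def are_parity(g: Graph, u: int, v: int) -> bool:
    """Parity (twin) test; reflexively true for ``u == v``."""
    _check_vertex(g, u)
    _check_vertex(g, v)
    if u == v:
        return True
    if not g.directed:
        return g.adj_out[u] - {v} == g.adj_out[v] - {u}
    return (
        len(g.adj_in[u]) == len(g.adj_in[v])
        and len(g.adj_out[u]) == len(g.adj_out[v])
        and g.adj_out[u] - {v} == g.adj_out[v] - {u}
        and g.adj_in[u] - {v} == g.adj_in[v] - {u}
    )


def parity_partition(g: Graph, representative: str = "min") -> ParityPartition:
    """Partition the vertex set into parity classes by pairwise tests.

    The partition is the union of all true pairs; transitivity is a proved
    property of the relation but is not assumed to skip checks.  The
    representative per class is its minimum (default) or maximum vertex id;
    the canonical form downstream is independent of this choice.
    """
    if representative not in ("min", "max"):
        raise ValueError(f"representative must be 'min' or 'max', got {representative!r}")
    parent = list(range(g.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(g.n):
        for v in range(u + 1, g.n):
            if are_parity(g, u, v):
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[max(ru, rv)] = min(ru, rv)

    groups: dict = {}
    for v in range(g.n):
        groups.setdefault(find(v), []).append(v)
    classes = sorted(groups.values(), key=lambda c: c[0])
    class_of = [0] * g.n
    reps = []
    for idx, members in enumerate(classes):
        for v in members:
            class_of[v] = idx
        reps.append(min(members) if representative == "min" else max(members))
    return ParityPartition(
        classes=tuple(frozenset(c) for c in classes),
        representatives=tuple(reps),
        class_of=tuple(class_of),
    )
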