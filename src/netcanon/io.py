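"""Edge-list TSV reading and writing.

Dialect: one edge per line, two tab-separated node names, ``#`` comment
lines, an optional ``source<TAB>target`` header (auto-detected).  Node names
are arbitrary strings mapped to dense integer ids in first-appearance
order, so a read-write-read round trip reproduces both the graph and the
name-to-id mapping exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .graph import Graph, GraphError, build_graph

logger = logging.getLogger("netcanon")


def read_edge_list(path, directed: bool = True) -> tuple:
    """Parse an edge-list TSV into ``(Graph, node_names)``.

    Duplicate edges are collapsed with a logged warning; a self-loop or a
    malformed line raises :class:`GraphError` naming the line number.
    """
    ids: dict = {}
    names: list = []
    pairs: list = []
    seen: set = set()
    duplicates = 0
    lines = Path(path).read_text().splitlines()
    first_data = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if first_data and [f.strip().lower() for f in fields] == ["source", "target"]:
            first_data = False
            continue
        first_data = False
        if len(fields) != 2:
            raise GraphError(
                f"{path}: line {lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}")
        src, dst = (f.strip() for f in fields)
        if src == dst:
            raise GraphError(f"{path}: line {lineno}: self-loop on {src!r}")
        for name in (src, dst):
            if name not in ids:
                ids[name] = len(names)
                names.append(name)
        u, v = ids[src], ids[dst]
        key = (u, v) if directed else (min(u, v), max(u, v))
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        pairs.append((u, v))
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, duplicates)
    g = build_graph(pairs, len(names), directed, labels=names)
    return g, tuple(names)


def write_edge_list(g: Graph, path) -> None:
    """Write the graph as edge-list TSV using its labels (or bare ids)."""
    names = g.labels if g.labels is not None else tuple(str(v) for v in range(g.n))
    lines = [f"{names[u]}\t{names[v]}" for u, v in sorted(g.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
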