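"""Programmatic graph generators: named small graphs, mesh and random
families, strongly regular examples, and synthetic transcriptional
regulation networks with planted motifs.

Every generator is deterministic given its parameters (and seed, where one
applies), so test inputs never need to be stored on disk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph import Graph, build_graph

#: Vertex ids of the Petersen fixture by display name.
PETERSEN_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I", "J")


def petersen() -> Graph:
    """The Petersen graph with named vertices A..J.

    Outer 5-cycle A-B-C-D-E, spokes A-F, B-G, C-I, D-H, E-J, inner 5-cycle
    F-I-J-G-H-F.  This particular naming is fixed so that W=(A, D, I) is a
    metric basis giving r(B|W)=(1,2,2), r(E|W)=(1,1,2), r(C|W)=(2,1,1);
    the test suite verifies those representations explicitly.
    """
    ix = {name: i for i, name in enumerate(PETERSEN_NAMES)}
    named = [
        ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A"),
        ("A", "F"), ("B", "G"), ("C", "I"), ("D", "H"), ("E", "J"),
        ("F", "I"), ("I", "J"), ("J", "G"), ("G", "H"), ("H", "F"),
    ]
    edges = [(ix[u], ix[v]) for u, v in named]
    return build_graph(edges, 10, directed=False, labels=PETERSEN_NAMES)


def petersen_ids(*names: str) -> tuple:
    """Vertex ids of the given Petersen display names, in argument order."""
    return tuple(PETERSEN_NAMES.index(n) for n in names)


def complete(q: int, directed: bool = False) -> Graph:
    pairs = list(itertools.permutations(range(q), 2)) if directed \
        else list(itertools.combinations(range(q), 2))
    return build_graph(pairs, q, directed)


def star(n_leaves: int) -> Graph:
    """Undirected star K_{1,m}: center 0, leaves 1..m (n = m + 1 vertices)."""
    return build_graph([(0, i) for i in range(1, n_leaves + 1)],
                       n_leaves + 1, directed=False)


def path(n: int, directed: bool = False) -> Graph:
    return build_graph([(i, i + 1) for i in range(n - 1)], n, directed)


def cycle(n: int, directed: bool = False) -> Graph:
    return build_graph([(i, (i + 1) % n) for i in range(n)], n, directed)


def mesh(side: int, dim: int) -> Graph:
    """dim-dimensional grid with ``side`` points per axis: side**dim
    vertices, edges between lattice points at unit distance."""
    if side < 1 or dim < 1:
        raise ValueError("mesh needs side >= 1 and dim >= 1")
    coords = list(itertools.product(range(side), repeat=dim))
    index = {c: i for i, c in enumerate(coords)}
    pairs = []
    for c in coords:
        for axis in range(dim):
            if c[axis] + 1 < side:
                nb = c[:axis] + (c[axis] + 1,) + c[axis + 1:]
                pairs.append((index[c], index[nb]))
    return build_graph(pairs, len(coords), directed=False)


def random_digraph(n: int, density: float, seed: int) -> Graph:
    """Each ordered pair (u, v), u != v, is an edge independently with
    probability ``density``."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.random((n, n)) < density
    np.fill_diagonal(a, False)
    us, vs = np.nonzero(a)
    return build_graph(list(zip(us.tolist(), vs.tolist())), n, directed=True)


def random_undirected(n: int, density: float, seed: int) -> Graph:
    """Erdos-Renyi G(n, p) on unordered pairs."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
             if rng.random() < density]
    return build_graph(pairs, n, directed=False)


def srg_paley(q: int = 13) -> Graph:
    """Paley graph on q vertices (q = 1 mod 4 prime): i ~ j iff i - j is a
    nonzero quadratic residue mod q.  Paley(13) is strongly regular with
    parameters (13, 6, 2, 3)."""
    if q % 4 != 1:
        raise ValueError("Paley graphs need q = 1 (mod 4)")
    residues = {(x * x) % q for x in range(1, q)}
    pairs = [(i, j) for i in range(q) for j in range(i + 1, q)
             if (i - j) % q in residues]
    return build_graph(pairs, q, directed=False)


def synthetic_trn(n: int = 200, n_ffl: int = 30, n_bifan: int = 10,
                  n_sim: int = 0, sim_targets: int = 12,
                  background_density: float = 0.03, seed: int = 0) -> Graph:
    """Synthetic transcriptional-regulation digraph with planted motifs.

    The planted feed-forward loops (3 vertices each), bi-fans (4 vertices)
    and single-input modules (1 + ``sim_targets`` vertices) occupy disjoint
    reserved vertex blocks that receive no background edges, so each planted
    instance is an induced occurrence by construction and the real count of
    each pattern is lower-bounded by the planted count.  The remaining
    vertices carry an Erdos-Renyi directed background at
    ``background_density``.
    """
    reserved = 3 * n_ffl + 4 * n_bifan + (1 + sim_targets) * n_sim
    if reserved > n:
        raise ValueError(
            f"planted structures need {reserved} vertices but n={n}")
    pairs = []
    v = 0
    for _ in range(n_ffl):
        x, y, z = v, v + 1, v + 2
        pairs += [(x, y), (y, z), (x, z)]
        v += 3
    for _ in range(n_bifan):
        x, y, z, w = v, v + 1, v + 2, v + 3
        pairs += [(x, z), (x, w), (y, z), (y, w)]
        v += 4
    for _ in range(n_sim):
        reg = v
        pairs += [(reg, reg + 1 + t) for t in range(sim_targets)]
        v += 1 + sim_targets
    rng = np.random.default_rng(seed)
    background = list(range(v, n))
    for u in background:
        for w in background:
            if u != w and rng.random() < background_density:
                pairs.append((u, w))
    return build_graph(pairs, n, directed=True)


@dataclass(frozen=True)
class GeneratorConfig:
    """Declarative request for one generated graph (used by the CLI)."""

    family: str
    n: int = 0
    side: int = 0
    dim: int = 2
    density: float = 0.0
    directed: bool = False
    planted_ffl: int = 30
    planted_bifan: int = 10
    planted_sim: int = 0
    seed: int = 0


def generate(cfg: GeneratorConfig) -> Graph:
    """Dispatch on ``cfg.family``; deterministic given the config."""
    fam = cfg.family
    if fam == "petersen":
        return petersen()
    if fam == "complete":
        return complete(cfg.n, cfg.directed)
    if fam == "star":
        return star(cfg.n - 1)
    if fam == "path":
        return path(cfg.n, cfg.directed)
    if fam == "cycle":
        return cycle(cfg.n, cfg.directed)
    if fam in ("mesh2d", "mesh3d", "mesh4d"):
        return mesh(cfg.side, {"mesh2d": 2, "mesh3d": 3, "mesh4d": 4}[fam])
    if fam == "random_digraph":
        return random_digraph(cfg.n, cfg.density, cfg.seed)
    if fam == "srg_paley":
        return srg_paley(cfg.n or 13)
    if fam == "synthetic_trn":
        return synthetic_trn(n=cfg.n or 200, n_ffl=cfg.planted_ffl,
                             n_bifan=cfg.planted_bifan, n_sim=cfg.planted_sim,
                             background_density=cfg.density or 0.03,
                             seed=cfg.seed)
    raise ValueError(f"unknown graph family {fam!r}")
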