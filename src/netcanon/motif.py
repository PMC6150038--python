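"""Motif patterns (feed-forward loop, single input module, bi-fan),
occurrence counting, and significance against a degree-preserving ensemble.

The fixed-size patterns (FFL, bi-fan) are counted through the full
enumeration + canonization path: their canonical labels are computed at
first use from hard-coded edge lists, so the counts stay consistent with
any internal labeling convention.  The single input module has variable
size and is counted by a direct rule-based scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .canonical import canonical_label
from .esu import census
from .graph import Graph, build_graph
from .randomize import build_ensemble

#: Default minimum number of targets for a single input module: the module
#: (regulator plus targets) must span more than 10 nodes.
DEFAULT_SIM_MIN_TARGETS = 10


@lru_cache(maxsize=None)
def ffl_label() -> str:
    """Canonical label of the coherent feed-forward loop x->y, y->z, x->z."""
    return canonical_label(build_graph([(0, 1), (1, 2), (0, 2)], 3, True)).label


@lru_cache(maxsize=None)
def bifan_label() -> str:
    """Canonical label of the bi-fan x->z, x->w, y->z, y->w."""
    return canonical_label(
        build_graph([(0, 2), (0, 3), (1, 2), (1, 3)], 4, True)
    ).label


@dataclass(frozen=True)
class PatternSpec:
    """A countable pattern.

    ``name`` is one of the built-ins (``A_FFL``, ``B_SIM``, ``C_BIFAN``) or
    any raw canonical-label string; ``k`` is the subgraph size for
    census-based patterns; ``min_targets`` applies to the SIM rule only.
    """

    name: str
    k: int | None = None
    min_targets: int | None = None


def ffl_spec() -> PatternSpec:
    return PatternSpec(name="A_FFL", k=3)


def sim_spec(min_targets: int = DEFAULT_SIM_MIN_TARGETS) -> PatternSpec:
    return PatternSpec(name="B_SIM", min_targets=min_targets)


def bifan_spec() -> PatternSpec:
    return PatternSpec(name="C_BIFAN", k=4)


def label_spec(label: str) -> PatternSpec:
    """Pattern given directly as a canonical-label string."""
    k = int(label.split(":", 1)[0])
    return PatternSpec(name=label, k=k)


def default_patterns() -> tuple:
    return (ffl_spec(), sim_spec(), bifan_spec())


def count_sim_modules(g: Graph, min_targets: int = DEFAULT_SIM_MIN_TARGETS) -> int:
    """Number of regulators x with at least ``min_targets`` targets whose
    sole in-neighbor is x (one count per qualifying regulator)."""
    count = 0
    for x in range(g.n):
        sole = sum(1 for y in g.adj_out[x] if g.adj_in[y] == frozenset({x}))
        if sole >= min_targets:
            count += 1
    return count


def count_pattern(g: Graph, spec: PatternSpec) -> int:
    """Occurrences of one pattern in ``g`` (directed input required)."""
    return count_patterns(g, (spec,))[spec.name]


def count_patterns(g: Graph, specs) -> dict:
    """Count several patterns, computing each needed subgraph census once."""
    if not g.directed:
        raise ValueError("motif patterns are directed; input graph is undirected")
    needed_k = set()
    for spec in specs:
        if spec.name != "B_SIM":
            if spec.k is None:
                raise ValueError(f"pattern {spec.name!r} needs a subgraph size k")
            needed_k.add(spec.k)
    censuses = {k: census(g, k) if g.n >= k else None for k in needed_k}
    out = {}
    for spec in specs:
        if spec.name == "B_SIM":
            mt = spec.min_targets or DEFAULT_SIM_MIN_TARGETS
            out[spec.name] = count_sim_modules(g, mt)
            continue
        label = {"A_FFL": ffl_label, "C_BIFAN": bifan_label}.get(spec.name, lambda s=spec: s.name)()
        c = censuses[spec.k]
        out[spec.name] = 0 if c is None else c.counts.get(label, 0)
    return out


@dataclass(frozen=True)
class PatternStats:
    """Significance of one pattern's real count against an ensemble.

    ``z_score`` and ``p_normal`` are ``None`` when the ensemble standard
    deviation is zero or no ensemble was run; ``p_empirical`` is the plain
    fraction of ensemble members whose count is >= the real count (it can
    legitimately be 0).
    """

    real_count: int
    ensemble_mean: float | None = None
    ensemble_sd: float | None = None
    z_score: float | None = None
    p_empirical: float | None = None
    p_normal: float | None = None


def significance(real_count: int, ensemble_counts) -> PatternStats:
    """Population mean/sd, z-score, empirical and normal-tail p-values."""
    counts = np.asarray(list(ensemble_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("ensemble is empty")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    p_emp = float((counts >= real_count).sum() / counts.size)
    if sd == 0:
        return PatternStats(real_count=real_count, ensemble_mean=mean,
                            ensemble_sd=sd, z_score=None,
                            p_empirical=p_emp, p_normal=None)
    z = (real_count - mean) / sd
    return PatternStats(real_count=real_count, ensemble_mean=mean,
                        ensemble_sd=sd, z_score=z, p_empirical=p_emp,
                        p_normal=float(norm.sf(z)))


def significance_from_moments(real_count: int, mean: float, sd: float) -> PatternStats:
    """Z-score and normal-tail p-value from a reported ensemble mean and
    standard deviation (no empirical fraction without the raw counts)."""
    if sd == 0:
        return PatternStats(real_count=real_count, ensemble_mean=mean,
                            ensemble_sd=sd)
    z = (real_count - mean) / sd
    return PatternStats(real_count=real_count, ensemble_mean=mean,
                        ensemble_sd=sd, z_score=z, p_normal=float(norm.sf(z)))


@dataclass(frozen=True)
class MotifReport:
    """Full motif-analysis result; a pure function of its inputs."""

    patterns: dict
    n_random: int
    switch_factor: float
    seed: int
    ensemble_counts: dict

    def to_tsv(self) -> str:
        cols = ["pattern", "real_count", "ensemble_mean", "ensemble_sd",
                "z_score", "p_empirical", "p_normal"]
        lines = ["\t".join(cols)]
        for name in self.patterns:
            st = self.patterns[name]
            row = [name, str(st.real_count)]
            for v in (st.ensemble_mean, st.ensemble_sd, st.z_score,
                      st.p_empirical, st.p_normal):
                row.append("NA" if v is None else format(v, ".6g"))
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self, include_ensemble: bool = False) -> str:
        obj = {
            "n_random": self.n_random,
            "switch_factor": self.switch_factor,
            "seed": self.seed,
            "patterns": {
                name: {
                    "real_count": st.real_count,
                    "ensemble_mean": st.ensemble_mean,
                    "ensemble_sd": st.ensemble_sd,
                    "z_score": st.z_score,
                    "p_empirical": st.p_empirical,
                    "p_normal": st.p_normal,
                }
                for name, st in self.patterns.items()
            },
        }
        if include_ensemble:
            obj["ensemble_counts"] = {k: list(v)
                                      for k, v in self.ensemble_counts.items()}
        return json.dumps(obj, indent=2, sort_keys=True)


def run_motif_analysis(g: Graph, patterns=None, n_random: int = 1000,
                       switch_factor: float = 10, seed: int = 0) -> MotifReport:
    """Count patterns in ``g``, build a degree-preserving ensemble, count
    patterns in every member, and score significance per pattern.

    With ``n_random=0`` only the real counts are reported and every
    significance field is ``None``.
    """
    if patterns is None:
        patterns = default_patterns()
    real = count_patterns(g, patterns)
    if n_random == 0:
        stats = {name: PatternStats(real_count=c) for name, c in real.items()}
        return MotifReport(patterns=stats, n_random=0,
                           switch_factor=switch_factor, seed=seed,
                           ensemble_counts={})
    ensemble = build_ensemble(g, n_random, switch_factor=switch_factor,
                              seed=seed)
    member_counts = {name: [] for name in real}
    for member in ensemble.graphs:
        counted = count_patterns(member, patterns)
        for name, c in counted.items():
            member_counts[name].append(c)
    stats = {name: significance(real[name], member_counts[name])
             for name in real}
    return MotifReport(
        patterns=stats, n_random=n_random, switch_factor=switch_factor,
        seed=seed,
        ensemble_counts={k: tuple(v) for k, v in member_counts.items()},
    )
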