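"""Metric representations, resolving-set tests, and exhaustive basis search.

A vertex subset ``W = (w1, ..., ws)`` resolves a target set when every two
targets have distinct metric representations ``r(v|W) = (d(v, w1), ...,
d(v, ws))``.  The smallest resolving sets (metric bases) give the metric
dimension; restricting both candidates and targets to one representative per
parity class gives the advanced variant and its (never larger) advanced
metric dimension.

For directed graphs each coordinate is the ordered distance pair
``(d(v, w), d(w, v))``: the pair is isomorphism-invariant and strictly more
discriminating than a one-way distance, which keeps dimensions small on
digraphs with unreachable pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import DistanceTable, Graph, all_pairs_distances
from .parity import ParityPartition


class SearchCapExceeded(RuntimeError):
    """Exhaustive subset search would exceed the configured work cap."""


#: Default cap on the number of candidate subsets examined per search.
DEFAULT_MAX_COMBINATIONS = 5_000_000


@dataclass(frozen=True)
class ResolvingSearchResult:
    """Outcome of an exhaustive minimum-(advanced-)resolving-set search.

    ``bases`` holds every vertex combination (sorted tuples, lexicographic
    order) of cardinality ``dimension`` that resolves the target set; the
    collection is complete, which the canonical label's lex-min requires.
    """

    dimension: int
    bases: tuple
    advanced: bool


def metric_representation(dt: DistanceTable, v: int, W: Sequence[int],
                          directed: bool) -> tuple:
    """``r(v|W)`` in W order; directed entries are ``(d(v,w), d(w,v))`` pairs."""
    d = dt.dist_out
    if directed:
        return tuple((int(d[v, w]), int(d[w, v])) for w in W)
    return tuple(int(d[v, w]) for w in W)


def _rep_rows(dt: DistanceTable, W: Sequence[int], targets: Sequence[int],
              directed: bool) -> np.ndarray:
    """Representation matrix: one row per target, coordinates in W order."""
    t = np.asarray(targets, dtype=np.intp)
    w = np.asarray(W, dtype=np.intp)
    fwd = dt.dist_out[np.ix_(t, w)]
    if not directed:
        return fwd
    rev = dt.dist_out[np.ix_(w, t)].T
    rows = np.empty((len(t), 2 * len(w)), dtype=dt.dist_out.dtype)
    rows[:, 0::2] = fwd
    rows[:, 1::2] = rev
    return rows


def is_resolving(dt: DistanceTable, W: Sequence[int], targets: Sequence[int],
                 directed: bool) -> bool:
    """True iff all targets have pairwise-distinct representations w.r.t. W."""
    targets = sorted(targets)
    if len(targets) <= 1:
        return True
    if len(W) == 0:
        return False
    rows = _rep_rows(dt, list(W), targets, directed)
    seen = {r.tobytes() for r in rows}
    return len(seen) == len(targets)


def _search(dt: DistanceTable, candidates: Sequence[int], targets: Sequence[int],
            directed: bool, advanced: bool, max_combinations: int) -> ResolvingSearchResult:
    """Increasing-cardinality exhaustive search; all bases of the first
    cardinality with a hit are retained."""
    candidates = sorted(candidates)
    targets = sorted(targets)
    examined = 0
    for s in range(0, len(candidates) + 1):
        hits = []
        for combo in itertools.combinations(candidates, s):
            examined += 1
            if examined > max_combinations:
                raise SearchCapExceeded(
                    f"resolving-set search exceeded {max_combinations} subset "
                    f"tests at cardinality {s} over {len(candidates)} candidates"
                )
            if is_resolving(dt, combo, targets, directed):
                hits.append(combo)
        if hits:
            return ResolvingSearchResult(dimension=s, bases=tuple(hits),
                                         advanced=advanced)
    raise AssertionError("the full candidate set must resolve its own members")


def minimum_resolving_sets(g: Graph, dt: DistanceTable | None = None,
                           max_combinations: int = DEFAULT_MAX_COMBINATIONS,
                           ) -> ResolvingSearchResult:
    """All metric bases of ``g``; ``dimension`` is the metric dimension.

    Enumerates subsets of the whole vertex set in increasing cardinality and
    returns every resolving combination at the first cardinality where one
    exists (for K_n this terminates at n-1).
    """
    if dt is None:
        dt = all_pairs_distances(g)
    return _search(dt, range(g.n), range(g.n), g.directed, advanced=False,
                   max_combinations=max_combinations)


def minimum_advanced_resolving_sets(g: Graph, pp: ParityPartition,
                                    dt: DistanceTable | None = None,
                                    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
                                    ) -> ResolvingSearchResult:
    """All minimum advanced resolving sets; ``dimension`` is the advanced
    metric dimension.

    Candidates and targets are both the parity-class representatives.  With a
    single class (e.g. complete graphs) the empty set resolves trivially and
    the dimension is 0; within-class order is immaterial for the canonical
    form, so nothing is lost.
    """
    if dt is None:
        dt = all_pairs_distances(g)
    return _search(dt, pp.representatives, pp.representatives, g.directed,
                   advanced=True, max_combinations=max_combinations)
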