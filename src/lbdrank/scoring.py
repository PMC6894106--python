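"""Hybrid direct + indirect scoring and min-max-normalized ranking.

For a target entity A and candidate C the score is

    Y = Y_direct + Y_indirect
    Y_direct   = S(A,C) * (2*alpha + beta)
    Y_indirect = sum over intermediates B_i of  X_i
    X_i        = S(A,B_i) * a_i  +  S(B_i,C) * b_i

where alpha/beta split the pair's co-occurrences into repeated-within-abstract
vs once-per-abstract occurrences, a_i and b_i are the total co-occurrence
counts of the two legs through B_i, and S is a semantic relatedness provider
(typically cosine similarity from a corpus- and thesaurus-trained embedding).
X_i equals the frequency-weighted average relatedness of the two legs times
the link count (a_i + b_i), so high-relatedness, well-travelled indirect
paths raise a pair's score even when it never co-occurs directly — the
literature-based-discovery (ABC) setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from sklearn.base import BaseEstimator

from .cooccurrence import CooccurrenceGraph, build_graph
from .relations_io import RelationRecord
from .relatedness import RelatednessProvider


@dataclass(frozen=True)
class PathScore:
    """One indirect A-B-C path: relatedness and co-occurrence of both legs."""

    intermediate: str
    s_ab: float
    a: int
    s_bc: float
    b: int

    @property
    def x(self) -> float:
        return self.s_ab * self.a + self.s_bc * self.b


@dataclass
class ScoredPair:
    target: str
    candidate: str
    y_direct: float
    y_indirect: float
    n_intermediates: int
    normalized: float | None = None

    @property
    def y_total(self) -> float:
        return self.y_direct + self.y_indirect


@dataclass
class RankedList:
    """Scored candidates for one target, sorted descending by total score.

    ``normalized`` on each item is the min-max rescaling of ``y_total`` over
    the list: the top item maps to 1, the bottom to 0; a degenerate all-equal
    list maps every item to 1.0.
    """

    target: str
    items: list[ScoredPair] = field(default_factory=list)
    score_min: float = 0.0
    score_max: float = 0.0

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def rank_of(self, candidate: str) -> int | None:
        """1-based rank of a candidate, or None if not in the list."""
        for i, item in enumerate(self.items):
            if item.candidate == candidate:
                return i + 1
        return None

    def top(self, n: int) -> list[ScoredPair]:
        return self.items[:n]


def direct_score(s: float, alpha: int, beta: int) -> float:
    """Relatedness-weighted direct co-occurrence score S * (2*alpha + beta).

    Occurrences from abstracts where the pair repeats (alpha) count double,
    rewarding within-abstract repetition over breadth of mention.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    return s * (2 * alpha + beta)


def path_score(s_ab: float, a: int, s_bc: float, b: int) -> float:
    """Indirect path score X = S_AB*a + S_BC*b for one intermediate.

    Equals the weighted-average relatedness of the two legs times the link
    count (a + b).
    """
    if a < 1 or b < 1:
        raise ValueError("leg co-occurrence counts must be >= 1")
    return s_ab * a + s_bc * b


def indirect_relatedness(s_ab: float, a: int, s_bc: float, b: int) -> float:
    """Frequency-weighted average relatedness [S_AB*a + S_BC*b] / (a + b).

    Lies between min(S_AB, S_BC) and max(S_AB, S_BC).
    """
    if a + b <= 0:
        raise ValueError("a + b must be positive")
    return (s_ab * a + s_bc * b) / (a + b)


def indirect_score(
    graph: CooccurrenceGraph,
    provider: RelatednessProvider,
    a_entity: str,
    c_entity: str,
) -> tuple[float, list[PathScore]]:
    """Sum of path scores over every shared intermediate of the pair."""
    paths: list[PathScore] = []
    for mid in sorted(graph.intermediates(a_entity, c_entity)):
        leg_ab = graph.pair_stats(a_entity, mid)
        leg_bc = graph.pair_stats(mid, c_entity)
        assert leg_ab is not None and leg_bc is not None
        paths.append(
            PathScore(
                intermediate=mid,
                s_ab=provider.relatedness(a_entity, mid),
                a=leg_ab.total_count,
                s_bc=provider.relatedness(mid, c_entity),
                b=leg_bc.total_count,
            )
        )
    return sum(p.x for p in paths), paths


def total_score(
    graph: CooccurrenceGraph,
    provider: RelatednessProvider,
    a_entity: str,
    c_entity: str,
) -> ScoredPair:
    """Hybrid score Y = Y_direct + Y_indirect for one entity pair.

    A pair with no direct edge contributes Y_direct = 0, so purely hidden
    relations can still score through their intermediates.
    """
    stats = graph.pair_stats(a_entity, c_entity)
    if stats is None:
        y_direct = 0.0
    else:
        y_direct = direct_score(
            provider.relatedness(a_entity, c_entity), stats.alpha, stats.beta
        )
    y_indirect, paths = indirect_score(graph, provider, a_entity, c_entity)
    return ScoredPair(
        target=a_entity,
        candidate=c_entity,
        y_direct=y_direct,
        y_indirect=y_indirect,
        n_intermediates=len(paths),
    )


def _apply_minmax(items: list[ScoredPair]) -> tuple[float, float]:
    if not items:
        return (0.0, 0.0)
    totals = [it.y_total for it in items]
    lo, hi = min(totals), max(totals)
    for it in items:
        it.normalized = 1.0 if hi == lo else (it.y_total - lo) / (hi - lo)
    return lo, hi


def default_candidates(graph: CooccurrenceGraph, target: str) -> set[str]:
    """Nodes sharing an edge or at least one intermediate with the target."""
    direct = graph.neighbors(target)
    indirect = {n2 for n1 in direct for n2 in graph.neighbors(n1)}
    candidates = direct | indirect
    candidates.discard(target)
    return candidates


def rank_candidates(
    graph: CooccurrenceGraph,
    provider: RelatednessProvider,
    target: str,
    candidates: Iterable[str] | Literal["all"] = "all",
    direct_only: bool = False,
) -> RankedList:
    """Rank candidates for a target by the hybrid score, min-max normalized.

    ``candidates="all"`` scores every node with a direct edge or a shared
    intermediate with the target (``direct_only=True`` restricts to direct
    co-occurrence only). Ties break lexicographically on the candidate label.
    """
    if target not in graph:
        raise KeyError(f"unknown target {target!r}")
    if candidates == "all":
        pool = graph.neighbors(target) if direct_only else default_candidates(graph, target)
    else:
        pool = set(candidates) - {target}
    items = [total_score(graph, provider, target, c) for c in pool]
    items.sort(key=lambda it: (-it.y_total, it.candidate))
    ranked = RankedList(target=target, items=items)
    ranked.score_min, ranked.score_max = _apply_minmax(items)
    return ranked


def rank_by_cooccurrence(
    graph: CooccurrenceGraph,
    target: str,
    candidates: Iterable[str] | Literal["all"] = "all",
    direct_only: bool = False,
) -> RankedList:
    """Baseline ranking by raw co-occurrence total only (same normalization)."""
    if target not in graph:
        raise KeyError(f"unknown target {target!r}")
    if candidates == "all":
        pool = graph.neighbors(target) if direct_only else default_candidates(graph, target)
    else:
        pool = set(candidates) - {target}
    items = []
    for c in pool:
        stats = graph.pair_stats(target, c)
        total = float(stats.total_count) if stats is not None else 0.0
        items.append(
            ScoredPair(target=target, candidate=c, y_direct=total, y_indirect=0.0,
                       n_intermediates=0)
        )
    items.sort(key=lambda it: (-it.y_total, it.candidate))
    ranked = RankedList(target=target, items=items)
    ranked.score_min, ranked.score_max = _apply_minmax(items)
    return ranked


class HybridRanker(BaseEstimator):
    """Estimator interface over the hybrid scorer.

    ``fit`` aggregates relation records into the co-occurrence graph;
    ``rank`` scores candidates for a target against a relatedness provider.

    Parameters
    ----------
    provider : RelatednessProvider
        Semantic relatedness source (a fitted embedding model or a
        :class:`~lbdrank.relatedness.TableProvider`).
    direct_only : bool, default False
        Restrict the candidate universe to direct co-occurrers.

    Attributes
    ----------
    graph_ : CooccurrenceGraph
        Aggregated pair statistics after :meth:`fit`.
    """

    def __init__(self, provider: RelatednessProvider | None = None, direct_only: bool = False):
        self.provider = provider
        self.direct_only = direct_only

    def fit(self, records: Sequence[RelationRecord], y=None) -> "HybridRanker":
        self.graph_ = build_graph(records)
        return self

    def score_pair(self, a_entity: str, c_entity: str) -> ScoredPair:
        self._check_fitted()
        return total_score(self.graph_, self.provider, a_entity, c_entity)

    def rank(
        self, target: str, candidates: Iterable[str] | Literal["all"] = "all"
    ) -> RankedList:
        self._check_fitted()
        return rank_candidates(
            self.graph_, self.provider, target, candidates, direct_only=self.direct_only
        )

    def rank_baseline(
        self, target: str, candidates: Iterable[str] | Literal["all"] = "all"
    ) -> RankedList:
        self._check_fitted()
        return rank_by_cooccurrence(
            self.graph_, target, candidates, direct_only=self.direct_only
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "graph_"):
            raise RuntimeError("HybridRanker is not fitted; call fit(records) first")
        if self.provider is None:
            raise ValueError("a relatedness provider is required for scoring")


def write_ranked_list(ranked: RankedList, stream, top: int | None = None) -> None:
    """Tab-separated ranking output: rank, candidate, y_direct, y_indirect,
    y_total, n_intermediates, normalized."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w", encoding="utf-8")
        close = True
    try:
        stream.write("rank\tcandidate\ty_direct\ty_indirect\ty_total\tn_intermediates\tnormalized\n")
        for i, it in enumerate(ranked.items[:top], start=1):
            stream.write(
                f"{i}\t{it.candidate}\t{it.y_direct:.6f}\t{it.y_indirect:.6f}\t"
                f"{it.y_total:.6f}\t{it.n_intermediates}\t{it.normalized:.6f}\n"
            )
    finally:
        if close:
            stream.close()
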