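"""Aggregate relation records into per-pair co-occurrence statistics.

For each unordered entity pair the within-abstract mention count ``c_d`` is
computed per distinct PMID, then split into the two frequency classes the
direct score weights differently:

* ``alpha`` ("sum_same") — occurrences contributed by abstracts where the
  pair co-occurs two or more times;
* ``beta`` ("sum_different") — occurrences from abstracts where the pair
  co-occurs exactly once (equal to the number of such abstracts).

``alpha + beta == total_count`` holds on every edge by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import networkx as nx

from .relations_io import RelationRecord


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in lexicographic storage order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairStats:
    """Co-occurrence statistics of one unordered entity pair."""

    pair: tuple[str, str]
    total_count: int
    alpha: int
    beta: int
    abstracts_multi: int
    abstracts_single: int

    def __post_init__(self) -> None:
        if min(self.total_count, self.alpha, self.beta) < 0:
            raise ValueError("counts must be non-negative")
        if self.alpha + self.beta != self.total_count:
            raise ValueError(
                f"alpha + beta must equal total_count "
                f"({self.alpha} + {self.beta} != {self.total_count})"
            )
        if self.beta != self.abstracts_single:
            raise ValueError("beta must equal the number of single-occurrence abstracts")
        if self.alpha < 2 * self.abstracts_multi:
            raise ValueError("alpha must be >= 2 x abstracts_multi")


class CooccurrenceGraph:
    """Entities as nodes, :class:`PairStats` as edge payloads.

    Thin wrapper over an undirected :class:`networkx.Graph`; supports the
    shared-intermediate queries the indirect (ABC) score enumerates.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    @property
    def nx_graph(self) -> nx.Graph:
        return self._g

    def add_edge(self, stats: PairStats) -> None:
        a, b = stats.pair
        if a == b:
            raise ValueError(f"self-edge {a!r}")
        self._g.add_edge(a, b, stats=stats)

    def add_node(self, entity: str) -> None:
        self._g.add_node(entity)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, entity: str) -> bool:
        return entity in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, entity: str) -> set[str]:
        if entity not in self._g:
            raise KeyError(f"unknown entity {entity!r}")
        return set(self._g.neighbors(entity))

    def edges(self) -> Iterator[PairStats]:
        for _, _, data in self._g.edges(data=True):
            yield data["stats"]

    def pair_stats(self, a: str, b: str) -> PairStats | None:
        """Order-insensitive edge lookup; None when the pair never co-occurs."""
        if self._g.has_edge(a, b):
            return self._g.edges[a, b]["stats"]
        return None

    def intermediates(self, a: str, c: str) -> set[str]:
        """Entities B adjacent to both ``a`` and ``c``, excluding the pair itself."""
        if a not in self._g:
            raise KeyError(f"unknown entity {a!r}")
        if c not in self._g:
            raise KeyError(f"unknown entity {c!r}")
        shared = set(self._g.neighbors(a)) & set(self._g.neighbors(c))
        shared.discard(a)
        shared.discard(c)
        return shared

    # -- persistence: tab-separated edge list ---------------------------------

    def to_file(self, stream: IO[str] | str) -> None:
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w", encoding="utf-8")
            close = True
        try:
            for stats in sorted(self.edges(), key=lambda s: s.pair):
                a, b = stats.pair
                stream.write(
                    f"{a}\t{b}\t{stats.total_count}\t{stats.alpha}\t{stats.beta}\n"
                )
        finally:
            if close:
                stream.close()

    @classmethod
    def from_file(cls, stream: IO[str] | str) -> "CooccurrenceGraph":
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        graph = cls()
        try:
            for line in stream:
                if not line.strip():
                    continue
                a, b, total, alpha, beta = line.rstrip("\n").split("\t")
                total_i, alpha_i, beta_i = int(total), int(alpha), int(beta)
                # abstract counts are not persisted; reconstruct the implied
                # minima (beta singles; alpha spread over ceil(alpha/2)-like
                # multis is unknowable, use the loosest consistent value 0/...)
                n_multi = 0 if alpha_i == 0 else 1
                graph.add_edge(
                    PairStats(
                        pair=canonical_pair(a, b),
                        total_count=total_i,
                        alpha=alpha_i,
                        beta=beta_i,
                        abstracts_multi=n_multi if alpha_i >= 2 else 0,
                        abstracts_single=beta_i,
                    )
                )
        finally:
            if close:
                stream.close()
        return graph


def build_graph(records: Iterable[RelationRecord]) -> CooccurrenceGraph:
    """Aggregate records into a co-occurrence graph.

    Each record line (a sentence-level mention) contributes 1 to its
    abstract's count for the pair; distinct relation labels for the same pair
    within one abstract therefore count as separate occurrences.
    """
    per_abstract: Counter[tuple[tuple[str, str], int]] = Counter()
    for r in records:
        per_abstract[(canonical_pair(r.entity_a, r.entity_b), r.pmid)] += 1

    totals: dict[tuple[str, str], list[int]] = {}
    for (pair, _pmid), c in per_abstract.items():
        totals.setdefault(pair, []).append(c)

    graph = CooccurrenceGraph()
    for pair, counts in totals.items():
        alpha = sum(c for c in counts if c >= 2)
        singles = sum(1 for c in counts if c == 1)
        graph.add_edge(
            PairStats(
                pair=pair,
                total_count=sum(counts),
                alpha=alpha,
                beta=singles,
                abstracts_multi=sum(1 for c in counts if c >= 2),
                abstracts_single=singles,
            )
        )
    return graph


def intermediates(graph: CooccurrenceGraph, a_entity: str, c_entity: str) -> set[str]:
    """Shared neighbors of two entities (the ABC model's B set)."""
    return graph.intermediates(a_entity, c_entity)


def pair_stats(graph: CooccurrenceGraph, a_entity: str, c_entity: str) -> PairStats | None:
    """Order-insensitive :class:`PairStats` lookup; None if the pair has no edge."""
    return graph.pair_stats(a_entity, c_entity)
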