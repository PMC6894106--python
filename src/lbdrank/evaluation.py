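"""Ranked-retrieval evaluation against a reference entity set.

Protocol: take the top k = ceil(fraction * N) of a ranked candidate list and
intersect it with a curated reference set (e.g. a disease-gene list). Recall
is |hits| / |reference|. The precision denominator is configurable because
published variants of this protocol disagree: "min" (default) uses
min(k, |reference|), "k" uses the cutoff size, "reference" duplicates recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Mapping

from .relations_io import normalize_entity
from .scoring import RankedList


@dataclass(frozen=True)
class ReferenceSet:
    """Curated set of entities treated as relevant for one target."""

    entities: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("reference set is empty")

    @classmethod
    def from_labels(cls, labels: Iterable[str], label: str = "") -> "ReferenceSet":
        return cls(frozenset(normalize_entity(x) for x in labels), label=label)

    @classmethod
    def from_file(cls, stream: IO[str] | str, label: str = "") -> "ReferenceSet":
        """One entity per line, UTF-8."""
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        try:
            labels = [line.strip() for line in stream if line.strip()]
        finally:
            if close:
                stream.close()
        return cls.from_labels(labels, label=label)

    def __len__(self) -> int:
        return len(self.entities)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_measure: float
    k: int
    hits: frozenset[str] = field(default_factory=frozenset)

    def to_file(self, stream: IO[str] | str) -> None:
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w", encoding="utf-8")
            close = True
        try:
            stream.write(f"k\t{self.k}\n")
            stream.write(f"precision\t{self.precision:.6f}\n")
            stream.write(f"recall\t{self.recall:.6f}\n")
            stream.write(f"f_measure\t{self.f_measure:.6f}\n")
            stream.write("hits\t" + ",".join(sorted(self.hits)) + "\n")
        finally:
            if close:
                stream.close()


def topk_eval(
    ranked: RankedList,
    reference: ReferenceSet,
    fraction: float = 0.2,
    precision_denominator: Literal["min", "k", "reference"] = "min",
) -> EvalReport:
    """Precision/recall/F over the top ``fraction`` of a ranked list.

    k = ceil(fraction * len(ranked)); hits = top-k candidates found in the
    reference set; recall = |hits| / |reference|; F = 2PR/(P+R) (0 when both
    are 0).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(ranked) == 0:
        raise ValueError("ranked list is empty")
    k = math.ceil(fraction * len(ranked))
    top = {item.candidate for item in ranked.top(k)}
    hits = frozenset(top & reference.entities)
    denom = {
        "min": min(k, len(reference)),
        "k": k,
        "reference": len(reference),
    }[precision_denominator]
    precision = len(hits) / denom if denom else 0.0
    recall = len(hits) / len(reference)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalReport(precision=precision, recall=recall, f_measure=f, k=k, hits=hits)


def rank_positions(
    rankings: Mapping[str, RankedList], probes: Iterable[str]
) -> list[tuple[str, str, int | None]]:
    """1-based rank of each probe under each method.

    Returns (entity, method, rank) rows sorted by entity then method; a probe
    missing from a method's candidate universe yields rank None ("absent"),
    never 0.
    """
    rows: list[tuple[str, str, int | None]] = []
    for probe in sorted(set(probes)):
        for method in sorted(rankings):
            rows.append((probe, method, rankings[method].rank_of(probe)))
    return rows
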