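"""Synthetic relation-record corpora with planted, known structure.

The generator emulates the statistical setting the hybrid scorer assumes:

* a hub entity (the analysis target, e.g. a disease) with frequent *direct*
  partners — pairs that co-occur in many abstracts, sometimes more than once
  per abstract (exercising the alpha/beta split);
* *hidden* partners that never co-occur with the hub directly but share m
  intermediate entities with it, each leg of each intermediate path carrying
  a configurable co-occurrence mass and relatedness strength — the
  literature-based-discovery signal the indirect score is built to surface;
* a frequency-matched *direct-only control* pair: same total co-occurrence
  mass as one hidden pathway, but no intermediates, so raw co-occurrence
  ranks it far above the hidden pair while the hybrid score should not;
* synonym twins that appear in disjoint abstracts and are grouped in the
  emitted thesaurus (never co-occurring, so only thesaurus-specialized
  training can pull them together);
* uniform background noise pairs.

Everything is seeded; the same seed yields byte-identical outputs. The
ground truth records exact per-pair (total, alpha, beta) via an independent
recount of the emitted records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ReferenceSet
from .relatedness import TableProvider
from .relations_io import RelationRecord, Thesaurus


@dataclass(frozen=True)
class DirectPair:
    """Hub partner co-occurring directly: per-abstract rate, probability of a
    second within-abstract mention, planted relatedness, entity type."""

    entity: str
    rate: float = 0.5
    multi_p: float = 0.3
    s: float = 0.5
    entity_type: str = "GENE"


@dataclass(frozen=True)
class HiddenPair:
    """Hub partner with zero direct co-occurrence, linked through ``m``
    intermediates; each leg receives exactly ``leg_total`` mentions and
    planted relatedness ``strength``."""

    entity: str
    m: int = 5
    strength: float = 0.9
    leg_total: int = 24
    entity_type: str = "GENE"


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_abstracts: int = 120
    hub: str = "alzheimer's disease"
    hub_type: str = "DISEASE"
    direct_pairs: list[DirectPair] = field(
        default_factory=lambda: [
            DirectPair("app", rate=0.6, multi_p=0.3, s=0.45),
            DirectPair("tau", rate=0.5, multi_p=0.3, s=0.50),
            DirectPair("apoe", rate=0.3, multi_p=0.2, s=0.50),
            DirectPair("psen1", rate=0.2, multi_p=0.1, s=0.40),
        ]
    )
    hidden_pairs: list[HiddenPair] = field(
        default_factory=lambda: [HiddenPair("bace2", m=5, strength=0.9, leg_total=24)]
    )
    control: DirectPair | None = DirectPair("memantine", s=0.5, entity_type="DRUG")
    n_noise_entities: int = 10
    noise_rate: float = 0.1
    synonym_twins: list[str] = field(default_factory=lambda: ["app", "apoe"])
    twin_abstracts: int = 20
    seed: int = 0

    def validate(self) -> None:
        names = [self.hub] + [p.entity for p in self.direct_pairs]
        names += [h.entity for h in self.hidden_pairs]
        if self.control is not None:
            names.append(self.control.entity)
        if len(set(names)) != len(names):
            raise ValueError("entity roles must be distinct")
        if self.noise_rate > 0 and self.n_noise_entities < 2:
            raise ValueError("need >= 2 noise entities when noise_rate > 0")
        for p in self.direct_pairs:
            if not (0.0 <= p.rate <= 1.0 and 0.0 <= p.multi_p <= 1.0):
                raise ValueError(f"rates must be in [0, 1] for {p.entity}")
        for h in self.hidden_pairs:
            if h.m < 1:
                raise ValueError("hidden pairs need m >= 1 intermediates")
        known = set(names)
        for t in self.synonym_twins:
            if t not in known:
                raise ValueError(f"synonym twin base {t!r} is not a configured entity")


@dataclass
class SynthGroundTruth:
    hub: str
    pair_stats: dict[tuple[str, str], tuple[int, int, int]]  # (total, alpha, beta)
    hidden_entities: list[str]
    control_entity: str | None
    intermediates: dict[str, list[str]]  # hidden entity -> its B entities
    thesaurus_groups: list[frozenset[str]]
    reference_entities: frozenset[str]


@dataclass
class SynthResult:
    records: list[RelationRecord]
    thesaurus: Thesaurus
    relatedness: TableProvider
    reference: ReferenceSet
    ground_truth: SynthGroundTruth


def _recount(records: list[RelationRecord]) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Independent (total, alpha, beta) recount used as planted ground truth."""
    per: Counter[tuple[tuple[str, str], int]] = Counter()
    for r in records:
        pair = tuple(sorted((r.entity_a, r.entity_b)))
        per[(pair, r.pmid)] += 1
    out: dict[tuple[str, str], tuple[int, int, int]] = {}
    agg: dict[tuple[str, str], list[int]] = {}
    for (pair, _), c in per.items():
        agg.setdefault(pair, []).append(c)
    for pair, counts in agg.items():
        alpha = sum(c for c in counts if c >= 2)
        beta = sum(1 for c in counts if c == 1)
        out[pair] = (sum(counts), alpha, beta)
    return out


def generate(config: SynthConfig) -> SynthResult:
    """Generate a corpus realizing the configured rates under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_pmid = 1_000_000  # keeps pmids positive and visibly synthetic
    n = config.n_abstracts

    # sentence cursor per abstract so mention order is well defined
    cursor: Counter[int] = Counter()
    records: list[RelationRecord] = []

    def emit(pmid: int, a: str, ta: str, b: str, tb: str, label: str = "CO-OCCUR") -> None:
        records.append(
            RelationRecord(
                pmid=pmid,
                sentence_index=cursor[pmid],
                entity_a=a,
                type_a=ta,
                entity_b=b,
                type_b=tb,
                relation_label=label,
            )
        )
        cursor[pmid] += 1

    # direct hub partners: per-abstract Bernoulli(rate), 1 + Bernoulli(multi_p) mentions
    for pair in config.direct_pairs:
        for d in range(n):
            if rng.random() < pair.rate:
                mentions = 1 + (1 if rng.random() < pair.multi_p else 0)
                for _ in range(mentions):
                    emit(base_pmid + d, config.hub, config.hub_type, pair.entity, pair.entity_type)

    # hidden pathways: hub-B_j legs live in even abstracts, B_j-hidden legs in
    # odd ones, so the hidden pair never shares an abstract with the hub
    intermediates: dict[str, list[str]] = {}
    evens = [base_pmid + d for d in range(0, n, 2)]
    odds = [base_pmid + d for d in range(1, n, 2)]
    for hidden in config.hidden_pairs:
        mids = [f"{hidden.entity} link{j}" for j in range(1, hidden.m + 1)]
        intermediates[hidden.entity] = mids
        for mid in mids:
            for pmid in rng.choice(evens, size=hidden.leg_total, replace=True):
                emit(int(pmid), config.hub, config.hub_type, mid, "GENE")
            for pmid in rng.choice(odds, size=hidden.leg_total, replace=True):
                emit(int(pmid), mid, "GENE", hidden.entity, hidden.entity_type)

    # frequency-matched direct-only control: exactly the co-occurrence mass of
    # one hidden pathway (m * leg_total mentions), no intermediates
    if config.control is not None and config.hidden_pairs:
        h0 = config.hidden_pairs[0]
        mass = h0.m * h0.leg_total
        for pmid in rng.choice(base_pmid + np.arange(n), size=mass, replace=True):
            emit(int(pmid), config.hub, config.hub_type,
                 config.control.entity, config.control.entity_type)

    # background noise between dedicated noise entities
    noise = [f"compound {i}" for i in range(config.n_noise_entities)]
    for d in range(n):
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            i, j = rng.choice(len(noise), size=2, replace=False)
            emit(base_pmid + d, noise[int(i)], "DRUG", noise[int(j)], "DRUG")

    # synonym twins: appear only in reserved twin abstracts, paired with noise
    # entities, so a twin never co-occurs with its base token
    twin_groups: list[frozenset[str]] = []
    twin_base = base_pmid + n
    for t_i, base in enumerate(config.synonym_twins):
        twin = f"{base} syn"
        twin_groups.append(frozenset({base, twin}))
        for d in range(config.twin_abstracts):
            pmid = twin_base + t_i * config.twin_abstracts + d
            partner = noise[int(rng.integers(len(noise)))]
            emit(pmid, twin, "GENE", partner, "DRUG")

    thesaurus = Thesaurus(twin_groups, provenance="synthetic synonym twins") \
        if twin_groups else Thesaurus([], provenance="synthetic (empty)")

    # planted relatedness table
    scores: list[tuple[str, str, float]] = []
    for pair in config.direct_pairs:
        scores.append((config.hub, pair.entity, pair.s))
    if config.control is not None:
        scores.append((config.hub, config.control.entity, config.control.s))
    for hidden in config.hidden_pairs:
        for mid in intermediates[hidden.entity]:
            scores.append((config.hub, mid, hidden.strength))
            scores.append((mid, hidden.entity, hidden.strength))
    table = TableProvider(scores, default=0.0)

    reference_entities = frozenset(
        [p.entity for p in config.direct_pairs if p.entity_type == "GENE"]
        + [h.entity for h in config.hidden_pairs if h.entity_type == "GENE"]
    )
    reference = ReferenceSet(reference_entities, label="planted hub-related genes")

    ground_truth = SynthGroundTruth(
        hub=config.hub,
        pair_stats=_recount(records),
        hidden_entities=[h.entity for h in config.hidden_pairs],
        control_entity=config.control.entity if config.control is not None else None,
        intermediates=intermediates,
        thesaurus_groups=twin_groups,
        reference_entities=reference_entities,
    )
    return SynthResult(
        records=records,
        thesaurus=thesaurus,
        relatedness=table,
        reference=reference,
        ground_truth=ground_truth,
    )
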