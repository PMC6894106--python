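import numpy as np
import pytest

from lbdrank.cooccurrence import build_graph
from lbdrank.relatedness import TableProvider, corpus_from_records
from lbdrank.relations_io import RelationRecord
from lbdrank.synthetic import SynthConfig, generate

TYPES = ("GENE", "DRUG", "DISEASE", "OTHER")


def random_records(rng: np.random.Generator, n_records: int = 60,
                   n_entities: int = 8, n_abstracts: int = 10) -> list[RelationRecord]:
    """Small random record stream over a closed entity vocabulary."""
    entities = [f"ent{i}" for i in range(n_entities)]
    records = []
    for _ in range(n_records):
        i, j = rng.choice(n_entities, size=2, replace=False)
        records.append(
            RelationRecord(
                pmid=int(rng.integers(1, n_abstracts + 1)),
                sentence_index=int(rng.integers(0, 30)),
                entity_a=entities[int(i)],
                type_a=TYPES[int(rng.integers(4))],
                entity_b=entities[int(j)],
                type_b=TYPES[int(rng.integers(4))],
                relation_label="CO-OCCUR",
            )
        )
    return records


def random_provider(rng: np.random.Generator, entities: list[str]) -> TableProvider:
    """Random symmetric relatedness table over all pairs of ``entities``."""
    scores = []
    for i, a in enumerate(entities):
        for b in entities[i + 1:]:
            scores.append((a, b, float(rng.uniform(-1, 1))))
    return TableProvider(scores)


@pytest.fixture(scope="session")
def synth_result():
    return generate(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_graph(synth_result):
    return build_graph(synth_result.records)


@pytest.fixture(scope="session")
def synth_corpus(synth_result):
    return corpus_from_records(synth_result.records)
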