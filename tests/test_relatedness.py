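"""Relatedness providers: embeddings, COALS, random indexing, score tables."""

import io
import math

import numpy as np
import pytest

from lbdrank.relatedness import (
    CoalsModel,
    CorpusView,
    RandomIndexingModel,
    SkipGramEmbedding,
    SpecializedSkipGramEmbedding,
    TableProvider,
    corpus_from_records,
)
from lbdrank.relations_io import RelationRecord, Thesaurus


# ---------------------------------------------------------------- corpus view

def test_corpus_from_single_record():
    r = RelationRecord(19395124, 8, "mci", "DISEASE", "depression", "DISEASE", "CO-OCCUR")
    view = corpus_from_records([r])
    assert view.pmids == [19395124]
    assert view.documents == [["mci", "depression"]]


def test_corpus_token_count_is_twice_record_count(synth_result, synth_corpus):
    assert sum(len(d) for d in synth_corpus.documents) == 2 * len(synth_result.records)


def test_corpus_orders_by_sentence_index():
    recs = [
        RelationRecord(1, 5, "c", "GENE", "d", "GENE", "R"),
        RelationRecord(1, 2, "a", "GENE", "b", "GENE", "R"),
    ]
    assert corpus_from_records(recs).documents == [["a", "b", "c", "d"]]


def test_empty_corpus_rejected_by_trainers():
    for model in (SkipGramEmbedding(), CoalsModel(), RandomIndexingModel()):
        with pytest.raises(ValueError):
            model.fit([])


# ------------------------------------------------------------------- skipgram

@pytest.fixture(scope="module")
def tiny_corpus():
    """(gene1, gene2) always co-occur; gene9 lives in disjoint documents
    with a disjoint filler vocabulary."""
    rng = np.random.default_rng(0)
    docs = []
    for _ in range(100):
        docs.append(["gene1", "gene2"] + [f"w{int(i)}" for i in rng.integers(0, 6, size=4)])
        docs.append(["gene9"] + [f"v{int(i)}" for i in rng.integers(0, 6, size=3)])
    return docs


def test_skipgram_cooccurring_pair_beats_noncooccurring(tiny_corpus):
    wins = 0
    for seed in range(5):
        m = SkipGramEmbedding(dimension=24, epochs=3, seed=seed).fit(tiny_corpus)
        if m.relatedness("gene1", "gene2") > m.relatedness("gene1", "gene9"):
            wins += 1
    assert wins >= 4


def test_skipgram_deterministic_under_fixed_seed(tiny_corpus):
    a = SkipGramEmbedding(dimension=16, epochs=2, seed=3).fit(tiny_corpus)
    b = SkipGramEmbedding(dimension=16, epochs=2, seed=3).fit(tiny_corpus)
    assert np.array_equal(a.vectors_, b.vectors_)


def test_skipgram_self_similarity_and_symmetry(tiny_corpus):
    m = SkipGramEmbedding(dimension=16, epochs=1, seed=0).fit(tiny_corpus)
    for tok in list(m.vocabulary_)[:5]:
        assert m.relatedness(tok, tok) == 1.0
    assert m.relatedness("gene1", "gene9") == pytest.approx(m.relatedness("gene9", "gene1"))
    assert abs(m.relatedness("gene1", "gene2")) <= 1.0 + 1e-12


def test_skipgram_needs_two_tokens():
    with pytest.raises(ValueError):
        SkipGramEmbedding(dimension=8).fit([["only"], ["only"]])
    with pytest.raises(ValueError):
        SkipGramEmbedding(dimension=1).fit([["a", "b"]])


def test_uncovered_entity_scores_zero(tiny_corpus):
    m = SkipGramEmbedding(dimension=8, epochs=1, seed=0).fit(tiny_corpus)
    assert not m.coverage("never seen")
    assert m.relatedness("gene1", "never seen") == 0.0


# -------------------------------------------------------- specialized skipgram

def test_rate_zero_reproduces_plain_bit_for_bit(tiny_corpus):
    th = Thesaurus([["gene1", "gene9"]])
    plain = SkipGramEmbedding(dimension=16, epochs=2, seed=5).fit(tiny_corpus)
    spec = SpecializedSkipGramEmbedding(
        thesaurus=th, context_sample_rate=0.0, dimension=16, epochs=2, seed=5
    ).fit(tiny_corpus)
    assert np.array_equal(plain.vectors_, spec.vectors_)


def test_specialization_pulls_grouped_noncooccurring_pair_together(synth_result, synth_corpus):
    # synonym twins never share an abstract; the emitted thesaurus groups them
    groups = synth_result.ground_truth.thesaurus_groups
    wins = 0
    for seed in range(3):
        plain = SkipGramEmbedding(dimension=32, epochs=2, seed=seed).fit(synth_corpus.documents)
        spec = SpecializedSkipGramEmbedding(
            thesaurus=synth_result.thesaurus, context_sample_rate=0.5,
            dimension=32, epochs=2, seed=seed,
        ).fit(synth_corpus.documents)
        mean_plain = np.mean([plain.relatedness(*sorted(g)) for g in groups])
        mean_spec = np.mean([spec.relatedness(*sorted(g)) for g in groups])
        if mean_spec > mean_plain:
            wins += 1
    assert wins >= 2


def test_empty_thesaurus_falls_back_with_warning(tiny_corpus):
    with pytest.warns(UserWarning):
        spec = SpecializedSkipGramEmbedding(
            thesaurus=None, context_sample_rate=0.5, dimension=8, epochs=1, seed=1
        ).fit(tiny_corpus)
    plain = SkipGramEmbedding(dimension=8, epochs=1, seed=1).fit(tiny_corpus)
    assert np.array_equal(spec.vectors_, plain.vectors_)


# ---------------------------------------------------------------------- coals

def _coals_oracle(docs, window, max_columns):
    """Independent straight-line implementation of the COALS transform."""
    counts = {}
    freq = {}
    for doc in docs:
        for tok in doc:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = sorted(freq)
    cols = sorted(sorted(vocab, key=lambda t: (-freq[t], t))[:max_columns])
    for doc in docs:
        for t, center in enumerate(doc):
            for off in range(1, window + 1):
                for j in (t - off, t + off):
                    if 0 <= j < len(doc) and doc[j] in cols:
                        counts[(center, doc[j])] = counts.get((center, doc[j]), 0) + (
                            window - off + 1
                        )
    total = sum(counts.values())
    rowsum = {a: sum(v for (x, _), v in counts.items() if x == a) for a in vocab}
    colsum = {b: sum(v for (_, y), v in counts.items() if y == b) for b in cols}
    mat = {}
    for a in vocab:
        for b in cols:
            c = counts.get((a, b), 0)
            num = total * c - rowsum[a] * colsum[b]
            den = math.sqrt(rowsum[a] * (total - rowsum[a]) * colsum[b] * (total - colsum[b]))
            r = num / den if den > 0 else 0.0
            mat[(a, b)] = math.sqrt(r) if r > 0 else 0.0
    return vocab, cols, mat


def test_coals_matrix_matches_hand_oracle_on_toy_corpus():
    docs = [
        ["amyloid", "plaque", "brain", "tau", "plaque", "brain"],
        ["tau", "tangle", "brain", "amyloid", "plaque", "tangle"],
        ["drug", "trial", "brain", "drug", "tau", "amyloid"],
    ]
    model = CoalsModel(window=2, max_columns=4).fit(docs)
    vocab, cols, oracle = _coals_oracle(docs, window=2, max_columns=4)
    assert sorted(model.vocabulary_) == vocab
    assert model.column_tokens_ == cols
    for a in vocab:
        row = model.vectors_[model.vocabulary_[a]]
        for j, b in enumerate(cols):
            assert row[j] == pytest.approx(oracle[(a, b)], abs=1e-12)


def test_coals_cells_nonnegative_and_self_similarity(synth_corpus):
    model = CoalsModel(window=4, max_columns=16).fit(synth_corpus.documents)
    assert (model.vectors_ >= 0).all()
    tok = next(iter(model.vocabulary_))
    assert model.relatedness(tok, tok) == 1.0


def test_coals_invariant_to_document_order(synth_corpus):
    docs = list(synth_corpus.documents)
    a = CoalsModel(window=3, max_columns=12).fit(docs)
    b = CoalsModel(window=3, max_columns=12).fit(list(reversed(docs)))
    assert np.allclose(a.vectors_, b.vectors_)


def test_coals_config_error():
    with pytest.raises(ValueError):
        CoalsModel(max_columns=1).fit([["a", "b"]])


# ------------------------------------------------------------- random indexing

def test_ri_index_vectors_are_balanced_ternary(synth_corpus):
    m = RandomIndexingModel(dimension=64, nonzeros=8, seed=2).fit(synth_corpus.documents)
    iv = m.index_vectors_
    assert set(np.unique(iv)) <= {-1.0, 0.0, 1.0}
    assert (np.count_nonzero(iv, axis=1) == 8).all()
    assert (iv.sum(axis=1) == 0).all()


def test_ri_deterministic(synth_corpus):
    a = RandomIndexingModel(dimension=64, nonzeros=6, seed=9).fit(synth_corpus.documents)
    b = RandomIndexingModel(dimension=64, nonzeros=6, seed=9).fit(synth_corpus.documents)
    assert np.array_equal(a.vectors_, b.vectors_)


def test_ri_identical_contexts_give_cosine_one():
    docs = [["x", "a", "b"], ["y", "a", "b"]] * 5
    m = RandomIndexingModel(dimension=64, nonzeros=4, window=2, seed=0).fit(docs)
    assert m.relatedness("x", "y") == pytest.approx(1.0)


def test_ri_config_errors():
    with pytest.raises(ValueError):
        RandomIndexingModel(dimension=4, nonzeros=8).fit([["a", "b"]])
    with pytest.raises(ValueError):
        RandomIndexingModel(nonzeros=3).fit([["a", "b"]])


# ------------------------------------------------------------- table provider

def test_table_provider_symmetric_lookup_from_reported_pair():
    tp = TableProvider([("alzheimer's disease", "app", 0.427029)])
    assert tp.relatedness("app", "alzheimer's disease") == pytest.approx(0.427029)
    assert tp.relatedness("app", "app") == 1.0
    assert tp.relatedness("unknown", "pair") == 0.0


def test_table_provider_conflicting_duplicates_rejected():
    with pytest.raises(ValueError):
        TableProvider([("a", "b", 0.1), ("b", "a", 0.2)])
    # consistent duplicates are fine
    assert TableProvider([("a", "b", 0.1), ("b", "a", 0.1)]).relatedness("a", "b") == 0.1


def test_table_provider_file_roundtrip(tmp_path):
    tp = TableProvider([("a", "b", 0.25), ("a", "c", -0.5)])
    path = tmp_path / "scores.tsv"
    tp.to_file(str(path))
    loaded = TableProvider.from_file(str(path))
    assert loaded.relatedness("b", "a") == 0.25
    assert loaded.relatedness("c", "a") == -0.5


# ---------------------------------------------------------------- persistence

def test_embedding_save_load_roundtrip(tiny_corpus):
    m = SkipGramEmbedding(dimension=8, epochs=1, seed=0).fit(tiny_corpus)
    buf = io.StringIO()
    m.save(buf)
    buf.seek(0)
    loaded = SkipGramEmbedding(dimension=8).load_vectors(buf)
    assert loaded.vocabulary_ == m.vocabulary_
    assert np.array_equal(loaded.vectors_, m.vectors_)
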