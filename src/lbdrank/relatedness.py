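"""Semantic relatedness providers.

A relatedness provider maps an entity pair to a score S in [-1, 1]
(cosine-like): symmetric, with S(x, x) = 1 on covered entities. Four
trainable models are provided, all scikit-learn style estimators fit on
token documents (lists of normalized entity labels):

* :class:`SkipGramEmbedding` — skip-gram with negative sampling (SGNS).
* :class:`SpecializedSkipGramEmbedding` — SGNS augmented with thesaurus
  contexts: at each target step, with probability ``context_sample_rate``
  one extra (target, context) pair is trained, the context drawn uniformly
  from the target's synonym group. This specializes the space so that
  synonymous entities that never co-occur still end up close.
* :class:`CoalsModel` — COALS: ramped windowed counts, column truncation to
  the most frequent tokens, per-cell correlation transform, negative
  truncation, square root; similarity is the correlation of transformed rows.
* :class:`RandomIndexingModel` — sparse ternary index vectors accumulated
  over windowed contexts; similarity is the cosine of context vectors.

:class:`TableProvider` serves precomputed scores without any training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .relations_io import RelationRecord, Thesaurus


@runtime_checkable
class RelatednessProvider(Protocol):
    """Contract: symmetric pairwise relatedness over covered entities."""

    def relatedness(self, entity1: str, entity2: str) -> float: ...

    def coverage(self, entity: str) -> bool: ...


@dataclass
class CorpusView:
    """Per-abstract token sequences used as embedding training text."""

    pmids: list[int] = field(default_factory=list)
    documents: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def corpus_from_records(records: Sequence[RelationRecord]) -> CorpusView:
    """Bridge relation records to training text.

    Per PMID, one token sequence ordered by (sentence_index, input order);
    each record contributes its two entities as adjacent tokens, so the token
    multiset has size 2 x record count.
    """
    by_pmid: dict[int, list[tuple[int, int, str, str]]] = {}
    for i, r in enumerate(records):
        by_pmid.setdefault(r.pmid, []).append((r.sentence_index, i, r.entity_a, r.entity_b))
    view = CorpusView()
    for pmid in sorted(by_pmid):
        tokens: list[str] = []
        for _, _, a, b in sorted(by_pmid[pmid]):
            tokens.extend((a, b))
        view.pmids.append(pmid)
        view.documents.append(tokens)
    return view


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _build_vocab(documents: Iterable[Sequence[str]]) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for doc in documents:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {tok: i for i, tok in enumerate(sorted(counts))}
    freqs = np.array([counts[tok] for tok in sorted(counts)], dtype=float)
    return vocab, freqs


class _VectorModel(BaseEstimator):
    """Shared surface of fitted vector-space models: cosine relatedness,
    coverage, and plain-text persistence."""

    vocabulary_: dict[str, int]
    vectors_: np.ndarray

    def vector(self, token: str) -> np.ndarray:
        return self.vectors_[self.vocabulary_[token]]

    def coverage(self, entity: str) -> bool:
        return hasattr(self, "vocabulary_") and entity in self.vocabulary_

    def relatedness(self, entity1: str, entity2: str) -> float:
        if not (self.coverage(entity1) and self.coverage(entity2)):
            return 0.0
        if entity1 == entity2:
            return 1.0
        return cosine(self.vector(entity1), self.vector(entity2))

    def save(self, stream: IO[str] | str) -> None:
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w", encoding="utf-8")
            close = True
        try:
            meta = " ".join(f"{k}={v}" for k, v in sorted(self.get_params().items()))
            stream.write(f"#lbdrank-embedding method={type(self).__name__} {meta}\n")
            inv = sorted(self.vocabulary_, key=self.vocabulary_.get)
            for tok in inv:
                vec = " ".join(repr(float(x)) for x in self.vectors_[self.vocabulary_[tok]])
                stream.write(f"{tok}\t{vec}\n")
        finally:
            if close:
                stream.close()

    def load_vectors(self, stream: IO[str] | str) -> "_VectorModel":
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        vocab: dict[str, int] = {}
        rows: list[np.ndarray] = []
        try:
            for line in stream:
                if line.startswith("#") or not line.strip():
                    continue
                tok, vec = line.rstrip("\n").split("\t")
                vocab[tok] = len(rows)
                rows.append(np.array(vec.split(), dtype=float))
        finally:
            if close:
                stream.close()
        self.vocabulary_ = vocab
        self.vectors_ = np.vstack(rows) if rows else np.empty((0, 0))
        return self


def _sgns_fit(
    documents: Sequence[Sequence[str]],
    *,
    dimension: int,
    window: int,
    negatives: int,
    epochs: int,
    learning_rate: float,
    seed: int,
    thesaurus_groups: dict[int, np.ndarray] | None,
    context_sample_rate: float,
) -> tuple[dict[str, int], np.ndarray]:
    """Skip-gram with negative sampling, single-threaded and seed-deterministic.

    The thesaurus hook draws from an auxiliary RNG stream so that with
    ``context_sample_rate = 0`` (or no thesaurus) the main sampling stream —
    and hence the learned vectors — is bit-identical to plain SGNS under the
    same seed.
    """
    vocab, freqs = _build_vocab(documents)
    if len(vocab) < 2:
        raise ValueError("training requires a vocabulary of at least 2 tokens")

    main_ss, aux_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(main_ss)
    aux = np.random.default_rng(aux_ss)

    n_vocab = len(vocab)
    # unigram^{3/4} negative-sampling distribution
    noise = freqs**0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    w_in = (rng.random((n_vocab, dimension)) - 0.5) / dimension
    w_out = np.zeros((n_vocab, dimension))

    docs_idx = [np.array([vocab[t] for t in doc], dtype=np.intp) for doc in documents]

    def update(center: int, context: int, neg_rng: np.random.Generator) -> None:
        targets = np.empty(negatives + 1, dtype=np.intp)
        targets[0] = context
        targets[1:] = np.searchsorted(noise_cdf, neg_rng.random(negatives))
        labels = np.zeros(negatives + 1)
        labels[0] = 1.0
        v = w_in[center]
        outs = w_out[targets]
        g = (labels - expit(outs @ v)) * learning_rate
        w_in[center] = v + g @ outs
        np.add.at(w_out, targets, np.outer(g, v))

    for _ in range(epochs):
        for doc in docs_idx:
            n = len(doc)
            for t in range(n):
                center = int(doc[t])
                lo = max(0, t - window)
                hi = min(n, t + window + 1)
                for j in range(lo, hi):
                    if j == t:
                        continue
                    update(center, int(doc[j]), rng)
                if thesaurus_groups is not None and context_sample_rate > 0.0:
                    if aux.random() < context_sample_rate:
                        group = thesaurus_groups.get(center)
                        if group is not None and len(group):
                            extra = int(group[aux.integers(len(group))])
                            update(center, extra, aux)
                elif thesaurus_groups is not None:
                    aux.random()  # keep the aux stream advancing uniformly

    return vocab, w_in


class SkipGramEmbedding(_VectorModel):
    """Skip-gram with negative sampling over entity-token documents.

    Parameters
    ----------
    dimension : int, default 100
        Embedding dimension (>= 2).
    window : int, default 5
        Symmetric context window in tokens.
    negatives : int, default 5
        Negative samples per (target, context) pair, drawn from the
        unigram^0.75 noise distribution.
    epochs : int, default 5
    learning_rate : float, default 0.025
        Fixed SGD step (no decay; corpora here are small).
    seed : int, default 0
        Full determinism under a fixed seed (single worker).

    Attributes
    ----------
    vocabulary_ : dict mapping token to row index
    vectors_ : ndarray of shape (n_tokens, dimension), input vectors
    """

    def __init__(
        self,
        dimension: int = 100,
        window: int = 5,
        negatives: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.025,
        seed: int = 0,
    ) -> None:
        self.dimension = dimension
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    def _thesaurus_groups(self) -> dict[int, np.ndarray] | None:
        return None

    def _rate(self) -> float:
        return 0.0

    def fit(self, documents: Sequence[Sequence[str]], y=None) -> "SkipGramEmbedding":
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        documents = list(documents)
        if not documents:
            raise ValueError("corpus is empty")
        self._docs = documents
        self.vocabulary_, self.vectors_ = _sgns_fit(
            documents,
            dimension=self.dimension,
            window=self.window,
            negatives=self.negatives,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            seed=self.seed,
            thesaurus_groups=self._thesaurus_groups(),
            context_sample_rate=self._rate(),
        )
        del self._docs
        return self


class SpecializedSkipGramEmbedding(SkipGramEmbedding):
    """Skip-gram specialized with thesaurus contexts.

    Identical to :class:`SkipGramEmbedding` except that at each target-token
    training step, with probability ``context_sample_rate``, one additional
    (target, context) pair is trained where the context is sampled uniformly
    from the target's thesaurus group (restricted to in-vocabulary members).
    With ``context_sample_rate = 0`` the model reproduces plain skip-gram
    bit-for-bit under the same seed.
    """

    def __init__(
        self,
        thesaurus: Thesaurus | None = None,
        context_sample_rate: float = 0.5,
        dimension: int = 100,
        window: int = 5,
        negatives: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.025,
        seed: int = 0,
    ) -> None:
        super().__init__(
            dimension=dimension,
            window=window,
            negatives=negatives,
            epochs=epochs,
            learning_rate=learning_rate,
            seed=seed,
        )
        self.thesaurus = thesaurus
        self.context_sample_rate = context_sample_rate

    def _thesaurus_groups(self) -> dict[int, np.ndarray] | None:
        vocab, _ = _build_vocab(self._docs)
        if self.thesaurus is None or len(self.thesaurus) == 0:
            warnings.warn(
                "empty thesaurus: specialized skip-gram falls back to plain skip-gram",
                UserWarning,
                stacklevel=2,
            )
            return None
        groups: dict[int, np.ndarray] = {}
        for group in self.thesaurus.groups:
            members = sorted(m for m in group if m in vocab)
            for m in members:
                others = np.array([vocab[o] for o in members if o != m], dtype=np.intp)
                if len(others):
                    groups[vocab[m]] = others
        if not groups:
            warnings.warn(
                "thesaurus covers no corpus token: falling back to plain skip-gram",
                UserWarning,
                stacklevel=2,
            )
            return None
        return groups

    def _rate(self) -> float:
        return self.context_sample_rate


class CoalsModel(_VectorModel):
    """COALS relatedness model.

    Pipeline: (1) windowed co-occurrence counts with linearly ramped weights
    (``window - offset + 1`` for offset 1..window); (2) columns restricted to
    the ``max_columns`` most frequent tokens; (3) each cell replaced by the
    pairwise correlation statistic of its row/column margins; (4) negatives
    set to 0; (5) square root of positives. Similarity between two tokens is
    the Pearson correlation of their transformed row vectors.
    """

    def __init__(self, window: int = 4, max_columns: int = 14000) -> None:
        self.window = window
        self.max_columns = max_columns

    def fit(self, documents: Sequence[Sequence[str]], y=None) -> "CoalsModel":
        if self.max_columns < 2:
            raise ValueError("max_columns must be >= 2")
        documents = list(documents)
        if not documents:
            raise ValueError("corpus is empty")
        vocab, freqs = _build_vocab(documents)
        n = len(vocab)
        # column set: most frequent tokens, ties broken lexicographically
        order = sorted(range(n), key=lambda i: (-freqs[i], i))
        cols = sorted(order[: self.max_columns])
        col_pos = {v: j for j, v in enumerate(cols)}

        counts = np.zeros((n, len(cols)))
        for doc in documents:
            idx = [vocab[t] for t in doc]
            for t, center in enumerate(idx):
                for off in range(1, self.window + 1):
                    w = self.window - off + 1
                    for j in (t - off, t + off):
                        if 0 <= j < len(idx) and idx[j] in col_pos:
                            counts[center, col_pos[idx[j]]] += w

        total = counts.sum()
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        num = total * counts - row * col
        den = np.sqrt(row * (total - row)) * np.sqrt(col * (total - col))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        corr[corr < 0] = 0.0
        self.vocabulary_ = vocab
        self.vectors_ = np.sqrt(corr)
        self.column_tokens_ = [t for t, i in sorted(vocab.items(), key=lambda kv: kv[1]) if i in col_pos]
        return self

    def relatedness(self, entity1: str, entity2: str) -> float:
        if not (self.coverage(entity1) and self.coverage(entity2)):
            return 0.0
        if entity1 == entity2:
            return 1.0
        u = self.vector(entity1)
        v = self.vector(entity2)
        su, sv = u.std(), v.std()
        if su == 0.0 or sv == 0.0:
            return 1.0 if np.array_equal(u, v) else 0.0
        return float(np.corrcoef(u, v)[0, 1])


class RandomIndexingModel(_VectorModel):
    """Random indexing relatedness model.

    Each token receives a seeded sparse ternary index vector with
    ``nonzeros`` nonzero entries (half +1, half -1, so they sum to zero);
    context vectors accumulate the index vectors of windowed neighbors, and
    similarity is the cosine of context vectors.
    """

    def __init__(
        self, dimension: int = 512, nonzeros: int = 8, window: int = 4, seed: int = 0
    ) -> None:
        self.dimension = dimension
        self.nonzeros = nonzeros
        self.window = window
        self.seed = seed

    def fit(self, documents: Sequence[Sequence[str]], y=None) -> "RandomIndexingModel":
        if self.nonzeros % 2 != 0 or self.nonzeros < 2:
            raise ValueError("nonzeros must be a positive even number")
        if self.dimension < self.nonzeros:
            raise ValueError("dimension must be >= nonzeros")
        documents = list(documents)
        if not documents:
            raise ValueError("corpus is empty")
        vocab, _ = _build_vocab(documents)
        n = len(vocab)
        rng = np.random.default_rng(self.seed)
        index = np.zeros((n, self.dimension))
        for i in range(n):  # vocab is sorted, so assignment is label-stable
            pos = rng.choice(self.dimension, size=self.nonzeros, replace=False)
            half = self.nonzeros // 2
            index[i, pos[:half]] = 1.0
            index[i, pos[half:]] = -1.0
        context = np.zeros((n, self.dimension))
        for doc in documents:
            idx = [vocab[t] for t in doc]
            for t, center in enumerate(idx):
                lo = max(0, t - self.window)
                hi = min(len(idx), t + self.window + 1)
                for j in range(lo, hi):
                    if j != t:
                        context[center] += index[idx[j]]
        self.vocabulary_ = vocab
        self.index_vectors_ = index
        self.vectors_ = context
        return self


class TableProvider:
    """Relatedness lookup from a precomputed (entity, entity, score) table.

    Symmetric; S(x, x) = 1 implicitly; pairs absent from the table return
    ``default`` (0 by default, which drops an indirect path's contribution
    rather than inventing relatedness).
    """

    def __init__(
        self, scores: Iterable[tuple[str, str, float]] = (), default: float = 0.0
    ) -> None:
        self.default = default
        self._table: dict[tuple[str, str], float] = {}
        self._entities: set[str] = set()
        for a, b, s in scores:
            key = (a, b) if a <= b else (b, a)
            if key in self._table and abs(self._table[key] - float(s)) > 1e-12:
                raise ValueError(f"conflicting duplicate scores for pair {key}")
            self._table[key] = float(s)
            self._entities.update(key)

    def relatedness(self, entity1: str, entity2: str) -> float:
        if entity1 == entity2:
            return 1.0
        key = (entity1, entity2) if entity1 <= entity2 else (entity2, entity1)
        return self._table.get(key, self.default)

    def coverage(self, entity: str) -> bool:
        return entity in self._entities

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_file(cls, stream: IO[str] | str, default: float = 0.0) -> "TableProvider":
        """Load a tab-separated "entityA <TAB> entityB <TAB> score" table."""
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        scores = []
        try:
            for line in stream:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b, s = line.rstrip("\n").split("\t")
                scores.append((a, b, float(s)))
        finally:
            if close:
                stream.close()
        return cls(scores, default=default)

    def to_file(self, stream: IO[str] | str) -> None:
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w", encoding="utf-8")
            close = True
        try:
            for (a, b), s in sorted(self._table.items()):
                stream.write(f"{a}\t{b}\t{s!r}\n")
        finally:
            if close:
                stream.close()


# thin functional wrappers over the estimators


def train_skipgram(corpus: CorpusView, **config) -> SkipGramEmbedding:
    return SkipGramEmbedding(**config).fit(corpus.documents)


def train_specialized_skipgram(
    corpus: CorpusView, thesaurus: Thesaurus | None, **config
) -> SpecializedSkipGramEmbedding:
    return SpecializedSkipGramEmbedding(thesaurus=thesaurus, **config).fit(corpus.documents)


def build_coals(corpus: CorpusView, **config) -> CoalsModel:
    return CoalsModel(**config).fit(corpus.documents)


def build_random_indexing(corpus: CorpusView, **config) -> RandomIndexingModel:
    return RandomIndexingModel(**config).fit(corpus.documents)


def table_provider(
    scores: Iterable[tuple[str, str, float]], default: float = 0.0
) -> TableProvider:
    return TableProvider(scores, default=default)
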