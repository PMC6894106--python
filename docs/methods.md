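# Methods

## Model

`lbdrank` scores the association of a target entity A with a candidate C as
the sum of a direct and an indirect component over a sentence-level
co-occurrence graph built from extractor records.

**Direct score.** Each record line is one mention of an unordered entity
pair in one sentence of one abstract. Per abstract d the pair's mention
count c_d is computed; the total f = Σ c_d then splits into α = Σ_{c_d≥2} c_d
(occurrences from abstracts where the pair repeats, "sum_same") and
β = #{d : c_d = 1} ("sum_different"), so α + β = f holds on every edge and
is asserted throughout the test suite. The direct score is
S(A,C)·(2α + β): within-abstract repetition is treated as stronger evidence
than breadth of mention. Two readings of α are possible (a count of
abstracts versus a count of occurrences); we use summed occurrences, the
only reading under which the published worked example's arithmetic
(α + β = f and the printed direct score) is self-consistent. Distinct
relation labels for the same pair in one abstract count as separate
occurrences; relation labels are carried through parsing but do not enter
the scores.

**Indirect score.** For every intermediate B_i adjacent to both A and C
(length-2 paths only; longer chains are out of scope), the path score is
X_i = S(A,B_i)·a_i + S(B_i,C)·b_i with a_i, b_i the total co-occurrence
counts of the two legs. X_i is identically the frequency-weighted average
relatedness of the legs, [S·a + S·b]/(a+b), multiplied by the link count
(a+b); both forms are exposed (`path_score`, `indirect_relatedness`) and
their consistency is property-tested. Y_indirect sums X_i over all
intermediates. A pair with no direct edge can still score through its
intermediates — the literature-based-discovery case the method exists for.

**Ranking.** The default candidate universe for a target is every node with
a direct edge *or* at least one shared intermediate (a `direct_only` switch
restricts to direct co-occurrers). Candidates sort descending by Y with
lexicographic tie-break on the label (determinism); scores are min-max
normalized over the list. Degenerate all-equal lists normalize to 1.0.

## Relatedness providers

All providers satisfy S(x,y) = S(y,x) and S(x,x) = 1 on covered entities;
embedding-backed providers return cosines in [-1, 1]. Negative cosines are
passed through to the scores unmodified (no clamping). Pairs not covered by
a provider score 0, which drops that path's contribution rather than
inventing relatedness.

**Skip-gram with negative sampling** (`SkipGramEmbedding`). Implemented in
numpy: unigram^0.75 noise distribution, input vectors initialized uniformly
in ±0.5/d, zero-initialized output vectors, fixed symmetric window (not the
per-position sampled window of some implementations — determinism and
simplicity on small corpora), fixed learning rate 0.025 without decay.
Defaults: dimension 100, window 5, 5 negatives, 5 epochs. These are
standard small-corpus SGNS settings; the scorer is provider-pluggable, so
hyperparameter choice is not load-bearing. Single-threaded and bit-exactly
reproducible per seed.

**Thesaurus specialization** (`SpecializedSkipGramEmbedding`). At each
target-token step, with probability `context_sample_rate` (default 0.5) one
extra (target, context) pair is trained, the context drawn uniformly from
the target's thesaurus group (restricted to in-vocabulary members). All
thesaurus-related draws come from an auxiliary RNG stream spawned from the
seed, so with rate 0 — or an empty/uncovering thesaurus, which warns and
falls back — the main sampling stream is untouched and the vectors are
bit-identical to plain SGNS under the same seed (asserted in the suite).

**COALS** (`CoalsModel`). Ramped windowed counts (weight window−offset+1;
default window 4, i.e. weights 4,3,2,1), columns truncated to the
`max_columns` most frequent tokens, each cell replaced by the correlation
statistic of its margins, negatives zeroed, square root of positives;
similarity is the Pearson correlation of transformed row vectors. Published
one-line summaries of COALS sometimes describe summing row correlations
instead; we implement the canonical row-correlation similarity. A
constant-variance row is given similarity 0 to any non-identical row.

**Random indexing** (`RandomIndexingModel`). Seeded ternary index vectors
(`nonzeros` entries, half +1 and half −1, so each sums to zero; defaults
dimension 512, nonzeros 8, window 4), context vectors accumulate windowed
neighbors' index vectors, similarity is the cosine of context vectors.
Index-vector assignment iterates the sorted vocabulary, so it is stable
across runs and document orderings.

**Score tables** (`TableProvider`). Symmetric lookup of precomputed
(entity, entity, score) rows; conflicting duplicates are a load error;
uncovered pairs return the configured default (0).

## Synthetic corpus generator

The generator emulates the statistical structure the scorer assumes, not
biomedical language: a hub entity with (i) frequent direct partners whose
per-abstract mention count is 1 + Bernoulli(multi_p) — the simplest process
exercising the α/β split; (ii) hidden partners with zero direct
co-occurrence, connected through m intermediates whose legs carry exactly
`leg_total` mentions each and planted relatedness `strength` (defaults
m = 5, leg_total = 24, strength 0.9); (iii) a direct-only control pair whose
total co-occurrence mass equals one hidden pathway's (m·leg_total), so raw
co-occurrence ranks it far above the hidden pair; (iv) synonym twins
confined to reserved abstracts so they never co-occur with their base token,
emitted as thesaurus groups; and (v) uniform background noise pairs
(default rate 0.1 per abstract over 10 noise entities). Default corpus size
is 120 abstracts (200 for the embedding-specialization checks). Hidden legs
live in even abstracts and hidden-side legs in odd ones; co-occurrence is
record-based, so the hub and a hidden entity sharing an abstract without a
joint record does not create an edge.

Ground truth records exact per-pair (total, α, β) via an independent
recount of the emitted records, plus the planted partial order
(hidden above control under the hybrid score; the reverse under raw
co-occurrence). A relatedness table is emitted alongside the records so
scoring tests decouple from embedding-training stochasticity.

What passing tests show: the aggregation arithmetic, the score formulas,
the ranking mechanics, and the planted-signal recovery property under the
generator's conditions. What they do not show: performance on real
extractor output, whose entity-frequency distribution is heavily skewed,
whose extraction is noisy, and whose relatedness structure is not planted.

## Numerical and design choices

- Entity normalization: trim, case-fold, collapse internal whitespace;
  optional thesaurus canonicalization to the group's lexicographically
  smallest member (order-independent of group listing). Without
  normalization the graph fragments on case variants.
- PMIDs may carry thousands separators (stripped); a terminal `|` producing
  an empty 8th field is tolerated.
- Top-k evaluation: k = ceil(fraction·N). The precision denominator is
  genuinely ambiguous across published uses of this protocol, so it is a
  switch: `min` (default, |hits|/min(k,|reference|)), `k`, or `reference`.
  Recall is always |hits|/|reference|; F = 2PR/(P+R).
- Fixed-seed determinism end to end: every stochastic component takes a
  seed; the CLI's `synth`/`train`/`score` runs are byte-reproducible.
- Test problem sizes: random-graph oracles use ≤ 20-node graphs; the
  embedding checks train dimension 24–50 models on 100–240 document corpora,
  keeping the default suite under a minute.

## Known limitations

- The benefit of thesaurus specialization for *input-vector* cosine is
  corpus-dependent: on the generator's corpora it raises grouped-pair
  cosines consistently (asserted over seeds), but on adversarial toy corpora
  with fully disjoint context vocabularies the joint objective can leave
  input-input similarity unchanged or lower. The contract the package
  guarantees is the training procedure and its determinism, not a universal
  similarity improvement.
- Indirect evidence is length-2 only; no relation-type weighting; directed
  relations are not modeled.
- COALS and random indexing are implemented for ranking comparison at small
  scale; no sparse-matrix optimizations for very large vocabularies.
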