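# Methods

## Scope and model

`bioir` implements an ad hoc retrieval benchmarking pipeline for
fielded biomedical document collections: analysis, indexing, ranking,
pseudo-relevance feedback, demographic filtering and evaluation.  The
pipeline treats a retrieval experiment as a pure function of its
inputs — corpus, topics, qrels and a flat configuration — so any run
can be reproduced bit-for-bit from its recorded configuration.

## Text analysis

Queries and documents pass through the same chain: split on maximal
runs of non-alphanumeric characters (hyphens, punctuation and
parentheses are separators; digits are kept, so gene symbols like
CDK4 survive as `cdk4`), case-fold, drop stopwords, Porter-stem.

- **Stopwords**: the classic 33-word English search-engine list is the
  default; a one-word-per-line file can replace it.  Stopwords are
  removed before stemming, against the lowercase token.
- **Stemmer**: the classic Porter algorithm, implemented in
  `bioir.stemming` and verified against the standard test vectors.
  Tokens shorter than three characters or containing non-letters pass
  through unchanged.  Porter stems are not fixed points of the
  algorithm for every English word (e.g. *agree* → *agre* → *agr*),
  so the analysis-idempotence guarantee is asserted on the synthetic
  fixture vocabulary, whose tokens are trivially stable.
- The analyzer configuration is stored with the index so query-time
  analysis can never drift from index-time analysis.

## Index and statistics

The inverted index keeps per-field postings `term → [(doc_id, tf)]`
and per-field statistics: N (documents with a non-empty analyzed
field), document frequencies n_t, average analyzed length avgdl and
per-document lengths |D|.  Statistics are **per field**: each field
defines its own retrieval space, so a title match is normalized
against title lengths and the title document count.  Documents lacking
a field simply do not participate in that field's space.  An optional
aggregate field concatenates all other text fields at build time
(the composite "text" field of clinical-trials schemas).  Persistence
is a versioned JSON dump that stores the raw documents and re-derives
postings on load; at the desk scale the package targets (≤ a few
thousand documents in tests) rebuild cost is negligible and the dump
stays human-readable.

## Ranking

Two per-field scoring functions, combined across fields by weighted
maximum `s(Q,D) = max_f w_f · score_f` (disjunction-max semantics);
documents with score 0 are never returned, and ties are broken by
doc_id ascending for reproducibility.

- **BM25** uses the *ratio* form of IDF, `(N − n_t + 0.5)/(n_t + 0.5)`,
  deliberately without the logarithm: the ratio is strictly positive,
  so every matching term contributes.  The conventional smoothed log
  variant `ln(1 + ratio)` is available as `bm25_idf="log"` because
  Lucene-derived engines score that way; the default stays raw.
  Defaults k1 = 1.2, b = 0.75 (the standard Okapi settings).
- **DFR-InL2** uses base-2 logarithms (the convention of the
  divergence-from-randomness literature); the base is a single module
  constant.  The length-normalization hyperparameter c defaults to 1
  and must be positive.
- **Weighted queries** generalize the bag-of-terms sums: each distinct
  term's contribution is multiplied by its query weight — raw counts
  for plain queries (reproducing the bag sum exactly) and
  probabilities after RM3, which act as soft counts.  |Supp(Q)| in the
  DFR formula counts distinct terms regardless of weights.
- Search enumerates candidates from the postings of positive-weight
  fields only, so a query term absent from the whole corpus retrieves
  nothing, and a field with weight 0 can never influence scores.

## RM3 expansion

The expansion retrieves the top k documents with the *same* ranking
function and parameters later used for the final search, represents
each by the analyzed text of a chosen field (`rm_field`), estimates
`RM(t) ∝ Σ_D P(t|D)·r(D,Q)` with Dirichlet smoothing
`P(t|D) = (f(t,D) + μ·f(t,D_R)/|D_R|)/(|D| + μ)`, truncates to the m
most probable terms (ties broken lexicographically), renormalizes the
truncated model, and interpolates with the maximum-likelihood query
model at weight α.  Renormalizing after truncation keeps the output a
probability distribution; without it the interpolation weights would
depend on how much mass truncation discarded.  Defaults α = 0.3,
μ = 100, k = 3, m = 8 — a conservative, low-feedback setting
appropriate for high-precision biomedical queries.  Query terms absent
from the feedback documents receive zero relevance-model mass, so
normalizing over the feedback vocabulary equals normalizing over the
vocabulary united with the query.  A query that retrieves nothing (or
a degenerate zero-mass model) falls back to the original query with a
warning: one empty topic must not fail a benchmark run.

## Query formulation

Per-task defaults mirror common TREC practice: genomics 2004 topics
concatenate title + need + context; genomics 2005 uses the narrative;
the clinical-decision-support tasks use exactly one of
description/summary/note per run; precision-medicine topics use
"disease gene".  A `user_query` topic field overrides the default and
is parsed in a minimal weighted dialect (terms, parenthesized groups,
`^W` suffixes); group weights multiply the per-term count weights.
Rule-based rewrites implemented: disease/gene field boosting
(`(disease)^1−W (gene)^W`), the "solid tumor"^0.2 expansion for
non-blood cancers (skipped when the disease text contains "leukemia"
or the topic is in an explicit skip set, and applied at most once),
and the CDS task-B compositions (summary / diagnosis+objective /
all), with diagnosis-objective topics always falling back to summary
only.

## Demographic filtering

`parse_demographic` extracts the first integer preceding
"year(-)old" and the first whole-word male/female; failing both is an
error because the filter would be vacuous.  Matching is strict
boolean: age within the trial's inclusive bounds and gender equal
unless the trial accepts all.  Missing information never excludes —
absent bounds are open, and an unknown profile gender passes gender
checks — because eligibility data in real trial registries is sparse
and a benchmarking filter should not silently drop unannotated
trials.  The filter is a predicate applied before scoring, so the
filtered ranking is a subset of the unfiltered one with relative
order preserved.

## Evaluation

P@10 (divisor fixed at 10 even for shorter rankings), R-Prec
(precision at the topic's relevant-document count) and RR (reciprocal
rank of the first relevant document, 0 if none retrieved), following
the NIST reference-tool conventions: topics with no relevant document
are excluded from macro averages; judged topics absent from the run
score 0 on all metrics.  Internal evaluation consumes rankings in
run-file rank order.  Run files use the standard 6-column format with
scores printed to 6 significant digits.  The test suite checks every
metric against an independent evaluator written directly from the
metric definitions over raw run rows, on randomized fixtures with
continuous scores (so rank ties, where external tools differ in
tie-breaking, have probability zero).

## Synthetic collections

The generator emulates a planted-relevance test collection: background
field text drawn from a Zipf-distributed synthetic vocabulary
(`t000123`-style tokens, immune to stemming), topics with five unique
query tokens, and a configurable fraction (`relevant_term_overlap`) of
those tokens planted into each topic's relevant documents.  At overlap
0 a topic's terms occur nowhere (retrieval is empty); at overlap 1
every retrieved document is relevant, so a topic with ≥ 10 planted
documents scores P@10 = 1 by construction — the end-to-end sanity
anchor.  The clinical variant adds random eligibility bounds
(min age uniform on 0–59, max age above it, 30% of trials
unconstrained by age, gender uniform over male/female/all) and a
demographic per topic.  Defaults (200 documents, 10 topics, 5
relevant each, vocabulary 2,000, Zipf exponent 1.1) keep a full
build-search-evaluate cycle under a second; oracle-equivalence tests
scale to 500–1,000 documents.  All randomness flows from one integer
seed; identical spec and seed give byte-identical files.

What passing on these fixtures does **not** show: behaviour on real
biomedical language (morphology, synonymy, MeSH structure), corpus
scale beyond thousands of documents, or absolute metric values on
TREC collections — the planted construction makes relevance
detectable by term overlap alone.

## Numerical choices and degenerate inputs

- Ranking ties broken by doc_id ascending; relevance-model truncation
  ties lexicographic — both purely for determinism.
- Score agreement between indexed and brute-force ranking is asserted
  at 1e-9; probability sums at 1e-9; metric agreement at 1e-6.
- Empty analyzed queries are errors at search time but skipped topics
  (with a warning and an empty ranking) at pipeline level.
- Empty corpora yield N = 0 and avgdl = 0; scoring functions return 0
  for documents missing the scored field rather than dividing by a
  zero avgdl.

## Known limitations

- No phrase, proximity, wildcard or boolean query operators: the
  query dialect is purely disjunctive weighted terms.
- The raw-ratio IDF departs from Lucene-style BM25 scoring; rankings
  may therefore differ from search-engine deployments even with equal
  parameters (the `log` switch approximates them).
- infNDCG and sampled-judgement evaluation are not implemented.
- Parsers for raw MEDLINE / PMC NXML / ClinicalTrials.gov formats are
  out of scope; corpora must be converted to the canonical JSONL
  dialect first.
- The in-memory index targets desk-scale corpora (up to roughly 10^5
  short documents); there is no compression, mmap or incremental
  indexing.
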