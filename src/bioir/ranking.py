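"""Document ranking: BM25 and DFR-InL2 per field, combined by weighted
maximum across fields (disjunction-max semantics).

Two scoring functions are provided.

BM25 with the ratio form of inverse document frequency::

    BM25(D, Q) = sum_t w(t) * IDF(t) * f(t,D)*(k1+1) /
                   (f(t,D) + k1*(1 - b + b*|D|/avgdl))
    IDF(t)     = (N - n_t + 0.5) / (n_t + 0.5)

Note the IDF carries no logarithm, so it is strictly positive for any
admissible (N, n_t) and every matching term contributes a positive
score.  A ``bm25_idf="log"`` switch selects the conventional smoothed
log variant ln(1 + IDF) instead.

DFR-InL2 (inverse document-frequency model, Laplace after-effect,
length normalization 2), with logarithms base 2::

    DFR(D, Q) = sum_t w(t) * (1/|Supp(Q)|) * (1/(f'(t,D)+1)) *
                  f'(t,D) * log2((N+1)/(n_t+0.5))
    f'(t,D)   = f(t,D) * log2(1 + c * avgdl/|D|)

Query-term weights w(t) are raw occurrence counts for plain queries and
probabilities after RM3 expansion; either way each distinct term's
contribution is multiplied by its weight.  |Supp(Q)| is the number of
distinct query terms, independent of the weights.

A document's final score is ``max_f w_f * score_f(D, Q)`` over the
index fields f, each scored in its own statistical space (its own N,
avgdl, n_t).  Documents scoring 0 are never returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping

from .analysis import AnalyzerConfig, analyze
from .corpus import InvertedIndex

__all__ = [
    "WeightedQuery",
    "RankerParams",
    "ScoredRanking",
    "idf",
    "bm25_field_score",
    "dfr_field_score",
    "combined_score",
    "search",
]

# Base of the DFR logarithms, centralized: base 2 is the convention of
# the divergence-from-randomness literature.
_DFR_LOG_BASE = 2.0


def _log(x: float) -> float:
    return math.log(x, _DFR_LOG_BASE)


@dataclass(frozen=True)
class WeightedQuery:
    """A bag of analyzed terms with strictly positive weights.

    Weights are term counts f(t, Q) for unexpanded queries and
    probabilities P(t|Q) after RM3; zero-weight terms are dropped at
    construction.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {t: float(w) for t, w in self.weights.items() if w > 0}
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("query weights must be nonnegative")
        object.__setattr__(self, "weights", clean)

    @property
    def support(self) -> frozenset[str]:
        """Distinct query terms, Supp(Q)."""
        return frozenset(self.weights)

    @property
    def total_weight(self) -> float:
        """Sum of weights (|Q| for a raw count query)."""
        return sum(self.weights.values())

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def from_text(
        cls, text: str, analyzer: AnalyzerConfig | None = None
    ) -> "WeightedQuery":
        """Analyze free text and weight each term by its count."""
        counts: dict[str, float] = {}
        for t in analyze(text, analyzer):
            counts[t] = counts.get(t, 0.0) + 1.0
        return cls(counts)


@dataclass(frozen=True)
class RankerParams:
    """Ranking-function choice and its free parameters.

    ``field_weights`` maps field name -> nonnegative boost; fields
    absent from the map get weight 0 and never contribute.
    """

    method: str = "bm25"            # "bm25" | "dfr"
    k1: float = 1.2
    b: float = 0.75
    c: float = 1.0
    field_weights: Mapping[str, float] = dc_field(default_factory=dict)
    depth: int = 1000
    bm25_idf: str = "raw"           # "raw" (verbatim ratio) | "log"

    def __post_init__(self) -> None:
        if self.method not in ("bm25", "dfr"):
            raise ValueError(f"unknown ranking method: {self.method!r}")
        if self.bm25_idf not in ("raw", "log"):
            raise ValueError(f"unknown bm25_idf variant: {self.bm25_idf!r}")
        if self.k1 < 0:
            raise ValueError("k1 must be nonnegative")
        if not 0 <= self.b <= 1:
            raise ValueError("b must lie in [0, 1]")
        if self.method == "dfr" and self.c <= 0:
            raise ValueError("c must be positive for DFR")
        if self.field_weights and all(w <= 0 for w in self.field_weights.values()):
            raise ValueError("at least one field weight must be positive")
        if any(w < 0 for w in self.field_weights.values()):
            raise ValueError("field weights must be nonnegative")
        object.__setattr__(self, "field_weights", dict(self.field_weights))


@dataclass
class ScoredRanking:
    """Ordered retrieval result for one topic: (doc_id, score, rank)
    triples with ranks starting at 1, scores non-increasing, ties
    broken by doc_id ascending, and all scores strictly positive."""

    topic_id: str
    entries: list[tuple[str, float, int]]

    def doc_ids(self) -> list[str]:
        return [d for d, _, _ in self.entries]


def idf(n_docs: int, n_t: int, variant: str = "raw") -> float:
    """Inverse document frequency (N - n_t + 0.5) / (n_t + 0.5).

    The ratio form, used verbatim: no logarithm, hence always > 0.
    ``variant="log"`` returns the smoothed log form ln(1 + ratio).
    """
    if n_t <= 0 or n_t > n_docs:
        raise ValueError(f"n_t must satisfy 1 <= n_t <= N, got n_t={n_t}, N={n_docs}")
    ratio = (n_docs - n_t + 0.5) / (n_t + 0.5)
    if variant == "raw":
        return ratio
    if variant == "log":
        return math.log(1.0 + ratio)
    raise ValueError(f"unknown idf variant: {variant!r}")


def bm25_field_score(
    query: WeightedQuery,
    doc_id: str,
    field: str,
    index: InvertedIndex,
    params: RankerParams,
) -> float:
    """BM25 score of one document field against a weighted query.

    Terms absent from the document or from the field's vocabulary
    contribute 0.
    """
    st = index.stats[field]
    dl = st.doc_len.get(doc_id)
    if dl is None or st.n_docs == 0:
        return 0.0
    norm_len = 1.0 - params.b + params.b * dl / st.avgdl
    score = 0.0
    for term, weight in query.weights.items():
        n_t = st.df.get(term)
        if not n_t:
            continue
        tf = index.term_frequency(field, term, doc_id)
        if tf == 0:
            continue
        term_idf = idf(st.n_docs, n_t, params.bm25_idf)
        score += weight * term_idf * tf * (params.k1 + 1.0) / (
            tf + params.k1 * norm_len
        )
    return score


def dfr_field_score(
    query: WeightedQuery,
    doc_id: str,
    field: str,
    index: InvertedIndex,
    params: RankerParams,
) -> float:
    """DFR-InL2 score of one document field against a weighted query."""
    st = index.stats[field]
    dl = st.doc_len.get(doc_id)
    if dl is None or st.n_docs == 0:
        return 0.0
    supp = len(query)
    if supp == 0:
        return 0.0
    length_norm = _log(1.0 + params.c * st.avgdl / dl)
    score = 0.0
    for term, weight in query.weights.items():
        n_t = st.df.get(term)
        if not n_t:
            continue
        tf = index.term_frequency(field, term, doc_id)
        if tf == 0:
            continue
        tfn = tf * length_norm                      # f'(t, D)
        info = _log((st.n_docs + 1.0) / (n_t + 0.5))
        score += weight * (1.0 / supp) * (tfn / (tfn + 1.0)) * info
    return score


_FIELD_SCORERS: dict[str, Callable] = {
    "bm25": bm25_field_score,
    "dfr": dfr_field_score,
}


def combined_score(
    query: WeightedQuery,
    doc_id: str,
    index: InvertedIndex,
    params: RankerParams,
) -> float:
    """Final score s(Q, D): maximum of field-weight * per-field score
    over all schema fields; zero-weight fields contribute 0."""
    scorer = _FIELD_SCORERS[params.method]
    best = 0.0
    for field in index.schema:
        w = params.field_weights.get(field, 0.0)
        if w <= 0:
            continue
        s = w * scorer(query, doc_id, field, index, params)
        if s > best:
            best = s
    return best


def search(
    query: WeightedQuery,
    index: InvertedIndex,
    params: RankerParams,
    doc_filter: Callable[[str], bool] | None = None,
    topic_id: str = "",
) -> ScoredRanking:
    """Rank all documents with positive combined score.

    Results are sorted by score descending, ties broken by doc_id
    ascending, truncated at ``params.depth``.  ``doc_filter`` (e.g. the
    demographic predicate) drops documents before ranking.
    """
    if len(query) == 0:
        raise ValueError("cannot search with an empty query")
    candidates: set[str] = set()
    for field in index.schema:
        if params.field_weights.get(field, 0.0) <= 0:
            continue
        fp = index.postings[field]
        for term in query.support:
            for doc_id, _ in fp.get(term, ()):
                candidates.add(doc_id)
    scored = []
    for doc_id in candidates:
        if doc_filter is not None and not doc_filter(doc_id):
            continue
        s = combined_score(query, doc_id, index, params)
        if s > 0:
            scored.append((doc_id, s))
    scored.sort(key=lambda p: (-p[1], p[0]))
    del scored[params.depth:]
    entries = [(d, s, i + 1) for i, (d, s) in enumerate(scored)]
    return ScoredRanking(topic_id=topic_id, entries=entries)
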