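"""RM3 pseudo-relevance feedback.

The expansion treats the top-k retrieved documents D_R as if relevant,
estimates a relevance model over their terms, truncates it to the m
most probable terms, and interpolates with the original query:

    P(t|Q) = (1-alpha) * RM(t) + alpha * P0(t|Q)

with

    RM(t)   proportional to  sum_{D in D_R} P(t|D) * r(D, Q)
    P(t|D)  = (f(t,D) + mu * f(t,D_R)/|D_R|) / (|D| + mu)
    P0(t|Q) = f(t,Q) / |Q|

where r(D, Q) is the retrieval score of the *same* ranking function
(with the same free parameters) later used for the final search,
f(t,D_R) is the term's frequency across the whole pseudo-collection,
|D_R| its total word length, and mu the Dirichlet smoothing mass.
RM(t) is normalized over the terms of D_R united with the query terms,
so the expanded query is a probability distribution.

When a query retrieves nothing (or the relevance model degenerates to
zero mass) expansion is impossible; :func:`rm3_expand` then falls back
to the original query with a logged warning rather than failing the
run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

from .corpus import InvertedIndex
from .ranking import RankerParams, WeightedQuery, search

__all__ = [
    "RM3Params",
    "PseudoCollection",
    "RelevanceModel",
    "ExpansionImpossible",
    "pseudo_collection",
    "smoothed_doc_model",
    "estimate_relevance_model",
    "interpolate_and_truncate",
    "rm3_expand",
]

logger = logging.getLogger(__name__)


class ExpansionImpossible(Exception):
    """Raised when no pseudo-collection can be formed or the relevance
    model has zero mass; callers fall back to the unexpanded query."""


@dataclass(frozen=True)
class RM3Params:
    """Free parameters of the expansion.

    alpha: interpolation weight of the original query, in [0, 1].
    mu: Dirichlet smoothing mass (0 disables smoothing).
    k: number of feedback documents.
    m: number of relevance-model terms kept.
    rm_field: index field used to represent the feedback documents.
    """

    alpha: float = 0.3
    mu: float = 100.0
    k: int = 3
    m: int = 8
    rm_field: str = "abstract"

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.m < 1:
            raise ValueError("m must be at least 1")


@dataclass
class PseudoCollection:
    """Top-k feedback documents with their retrieval scores and the
    analyzed term list of the relevance-modelling field."""

    entries: list[tuple[str, float, list[str]]]   # (doc_id, r(D,Q), terms)
    total_length: int = 0                         # |D_R|
    collection_tf: dict[str, int] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.total_length = sum(len(terms) for _, _, terms in self.entries)
        tf: dict[str, int] = {}
        for _, _, terms in self.entries:
            for t in terms:
                tf[t] = tf.get(t, 0) + 1
        self.collection_tf = tf


@dataclass
class RelevanceModel:
    """Normalized term distribution P(t|Q), summing to 1."""

    probs: dict[str, float]


def pseudo_collection(
    query: WeightedQuery,
    index: InvertedIndex,
    ranker: RankerParams,
    params: RM3Params,
) -> PseudoCollection:
    """Retrieve the top min(k, available) documents with the same
    ranker used for the final search and represent each by the analyzed
    text of ``rm_field``."""
    ranking = search(query, index, ranker)
    top = ranking.entries[: params.k]
    if not top:
        raise ExpansionImpossible("query retrieved no documents")
    entries = [
        (doc_id, score, index.analyzed_field(doc_id, params.rm_field))
        for doc_id, score, _rank in top
    ]
    return PseudoCollection(entries=entries)


def smoothed_doc_model(
    term: str,
    entry: tuple[str, float, list[str]],
    pc: PseudoCollection,
    mu: float,
) -> float:
    """Dirichlet-smoothed document language model P(t|D) (Eq. above)."""
    _doc_id, _score, terms = entry
    dl = len(terms)
    if dl + mu == 0:
        raise ValueError("document length and mu are both zero")
    tf = sum(1 for t in terms if t == term)
    if pc.total_length > 0:
        background = pc.collection_tf.get(term, 0) / pc.total_length
    else:
        background = 0.0
    return (tf + mu * background) / (dl + mu)


def estimate_relevance_model(pc: PseudoCollection, mu: float) -> RelevanceModel:
    """Score every candidate term by sum_D P(t|D) * r(D,Q) and
    normalize to a distribution over the candidate set.

    The candidate set is the vocabulary of D_R; callers union in the
    query terms via interpolation (absent terms have RM mass 0 there).
    """
    raw: dict[str, float] = {}
    candidates = set(pc.collection_tf)
    for term in candidates:
        mass = 0.0
        for entry in pc.entries:
            _doc_id, score, _terms = entry
            mass += smoothed_doc_model(term, entry, pc, mu) * score
        if mass > 0:
            raw[term] = mass
    total = sum(raw.values())
    if total <= 0:
        raise ExpansionImpossible("relevance model has zero mass")
    return RelevanceModel(probs={t: v / total for t, v in raw.items()})


def interpolate_and_truncate(
    rm: RelevanceModel,
    query: WeightedQuery,
    alpha: float,
    m: int,
) -> WeightedQuery:
    """Keep the m most probable relevance-model terms (ties broken
    lexicographically), renormalize them, and interpolate with the
    maximum-likelihood query model P0(t|Q) = f(t,Q)/|Q|.

    The result is a probability-weighted query over the truncated terms
    united with the original query terms; weights sum to 1.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    ranked = sorted(rm.probs.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = dict(ranked[:m])
    kept_total = sum(kept.values())
    if kept_total > 0:
        kept = {t: v / kept_total for t, v in kept.items()}
    q_total = query.total_weight
    p0 = {t: w / q_total for t, w in query.weights.items()}
    out: dict[str, float] = {}
    for t in set(kept) | set(p0):
        out[t] = (1.0 - alpha) * kept.get(t, 0.0) + alpha * p0.get(t, 0.0)
    return WeightedQuery(out)


def rm3_expand(
    query: WeightedQuery,
    index: InvertedIndex,
    ranker: RankerParams,
    params: RM3Params,
) -> WeightedQuery:
    """Full RM3 expansion; returns the original query unchanged when
    expansion is impossible (nothing retrieved / degenerate model)."""
    try:
        pc = pseudo_collection(query, index, ranker, params)
        rm = estimate_relevance_model(pc, params.mu)
    except ExpansionImpossible as exc:
        logger.warning("RM3 expansion impossible (%s); using original query", exc)
        return query
    return interpolate_and_truncate(rm, query, params.alpha, params.m)
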