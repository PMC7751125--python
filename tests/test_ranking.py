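"""BM25 / DFR scoring: analytic identities, invariants and the
brute-force full-scan oracle."""

import math

import numpy as np
import pytest

from bioir.corpus import FieldedDocument, build_index
from bioir.ranking import (
    RankerParams,
    WeightedQuery,
    bm25_field_score,
    combined_score,
    dfr_field_score,
    idf,
    search,
)

from oracles import brute_force_search


def test_idf_values():
    assert idf(1, 1) == pytest.approx(0.5 / 1.5)
    assert idf(2, 1) == pytest.approx(1.0)
    assert idf(1000, 1) == pytest.approx(999.5 / 1.5)


def test_idf_always_positive():
    for n_docs in (1, 2, 10, 1000):
        for n_t in range(1, n_docs + 1):
            assert idf(n_docs, n_t) > 0


def test_idf_domain_errors():
    with pytest.raises(ValueError):
        idf(10, 0)
    with pytest.raises(ValueError):
        idf(10, 11)


def test_idf_log_variant():
    assert idf(2, 1, "log") == pytest.approx(math.log(2.0))


@pytest.mark.parametrize("k1,b", [(0.0, 0.0), (1.2, 0.75), (2.0, 1.0)])
def test_bm25_equals_idf_at_average_length(analyzer, k1, b):
    """With f=1 and |D|=avgdl the saturation factor is identically 1,
    so the term score reduces to the IDF for any (k1, b)."""
    docs = [
        FieldedDocument("D1", {"t": "alpha beta gamma"}),
        FieldedDocument("D2", {"t": "delta epsilon zeta"}),
    ]
    index = build_index(docs, analyzer, ["t"])
    params = RankerParams(method="bm25", k1=k1, b=b, field_weights={"t": 1.0})
    query = WeightedQuery({"alpha": 1.0})
    score = bm25_field_score(query, "D1", "t", index, params)
    assert score == pytest.approx(idf(2, 1), abs=1e-12)


def test_bm25_absent_term_contributes_zero(small_index):
    params = RankerParams(field_weights={"abstract": 1.0})
    q = WeightedQuery({"nonexistent": 1.0})
    assert bm25_field_score(q, "D1", "abstract", small_index, params) == 0.0


def test_bm25_monotone_in_tf(analyzer):
    """For fixed statistics the term score strictly increases with
    f(t,D) and is bounded by weight * idf * (k1+1)."""
    docs = [FieldedDocument(f"D{i}", {"t": " ".join(["x"] * (i + 1)) + " pad"})
            for i in range(6)]
    index = build_index(docs, analyzer, ["t"])
    st = index.stats["t"]
    params = RankerParams(method="bm25", k1=1.2, b=0.0,
                          field_weights={"t": 1.0})
    q = WeightedQuery({"x": 1.0})
    scores = [bm25_field_score(q, f"D{i}", "t", index, params)
              for i in range(6)]
    assert all(a < b for a, b in zip(scores, scores[1:]))
    bound = idf(st.n_docs, st.df["x"]) * (params.k1 + 1)
    assert all(s < bound for s in scores)


def test_dfr_analytic_half(analyzer):
    """N=2, n_t=1, f=1, |D|=avgdl, c=1, single unit-weight term:
    f' = log2(2) = 1, so the score is (1/1)*(1/2)*1*log2(3/1.5) = 0.5."""
    docs = [
        FieldedDocument("D1", {"t": "alpha beta gamma"}),
        FieldedDocument("D2", {"t": "delta epsilon zeta"}),
    ]
    index = build_index(docs, analyzer, ["t"])
    params = RankerParams(method="dfr", c=1.0, field_weights={"t": 1.0})
    query = WeightedQuery({"alpha": 1.0})
    assert dfr_field_score(query, "D1", "t", index, params) == pytest.approx(0.5, abs=1e-12)


def test_dfr_monotone_in_c(small_index):
    """f'/(f'+1) grows with f', which grows with c."""
    q = WeightedQuery({"iron": 1.0})
    scores = []
    for c in (0.5, 1.0, 2.0, 8.0):
        params = RankerParams(method="dfr", c=c,
                              field_weights={"abstract": 1.0})
        scores.append(dfr_field_score(q, "D3", "abstract", small_index, params))
    assert all(a < b for a, b in zip(scores, scores[1:]))


def test_combined_score_is_weighted_max(small_index):
    """Hand-set field weights: the combination picks max(w_f * s_f)."""
    params_a = RankerParams(field_weights={"abstract": 1.0})
    params_t = RankerParams(field_weights={"title": 1.0})
    q = WeightedQuery({"iron": 1.0})
    s_abs = bm25_field_score(q, "D3", "abstract", small_index, params_a)
    s_tit = bm25_field_score(q, "D3", "title", small_index, params_t)
    assert s_abs > 0 and s_tit > 0
    combined = combined_score(q, "D3", small_index,
                              RankerParams(field_weights={"abstract": 1.0,
                                                          "title": 3.0}))
    assert combined == pytest.approx(max(s_abs, 3.0 * s_tit))
    # zero weights everywhere -> 0 would be rejected at params level
    only_abs = combined_score(q, "D3", small_index,
                              RankerParams(field_weights={"abstract": 1.0}))
    assert only_abs == pytest.approx(s_abs)


def test_zero_weight_field_never_changes_scores(fixture_index):
    q = WeightedQuery({"q000w0": 1.0, "q000w1": 1.0})
    base = RankerParams(field_weights={"abstract": 1.0})
    extra = RankerParams(field_weights={"abstract": 1.0, "title": 0.0})
    r1 = search(q, fixture_index, base)
    r2 = search(q, fixture_index, extra)
    assert r1.entries == r2.entries


def test_search_empty_query_errors(fixture_index):
    with pytest.raises(ValueError):
        search(WeightedQuery({}), fixture_index,
               RankerParams(field_weights={"abstract": 1.0}))


def test_search_unknown_terms_empty_ranking(fixture_index):
    r = search(WeightedQuery({"zzzznotaterm": 1.0}), fixture_index,
               RankerParams(field_weights={"abstract": 1.0, "title": 1.0}))
    assert r.entries == []


def test_tie_break_by_doc_id(analyzer):
    docs = [
        FieldedDocument("B", {"t": "alpha beta"}),
        FieldedDocument("A", {"t": "alpha beta"}),
        FieldedDocument("C", {"t": "gamma delta"}),
    ]
    index = build_index(docs, analyzer, ["t"])
    r = search(WeightedQuery({"alpha": 1.0}), index,
               RankerParams(field_weights={"t": 1.0}))
    assert r.doc_ids() == ["A", "B"]
    assert r.entries[0][1] == r.entries[1][1]


def test_ranking_invariants(fixture_index):
    q = WeightedQuery({"q000w0": 1.0, "t000001": 2.0})
    r = search(q, fixture_index,
               RankerParams(field_weights={"abstract": 1.0, "title": 1.0}))
    scores = [s for _, s, _ in r.entries]
    ranks = [k for _, _, k in r.entries]
    assert all(s > 0 for s in scores)
    assert scores == sorted(scores, reverse=True)
    assert ranks == list(range(1, len(ranks) + 1))


@pytest.mark.parametrize("method", ["bm25", "dfr"])
def test_search_matches_brute_force_oracle(fixture_collection, fixture_index,
                                           analyzer, method):
    """Index-accelerated search equals exhaustive per-document scoring
    (ordering exact, scores within 1e-9) for 50 random queries."""
    rng = np.random.default_rng(2024)
    vocab = sorted(fixture_index.stats["abstract"].df)
    field_weights = {"abstract": 1.0, "title": 2.0}
    params = RankerParams(method=method, field_weights=field_weights,
                          depth=100)
    for _ in range(50):
        n_terms = int(rng.integers(1, 5))
        terms = list(rng.choice(vocab, size=n_terms, replace=False))
        weights = {t: float(rng.integers(1, 4)) for t in terms}
        query = WeightedQuery(weights)
        got = search(query, fixture_index, params)
        expected = brute_force_search(
            fixture_collection.documents, analyzer, query.weights,
            method, field_weights, depth=100,
        )
        assert [d for d, _, _ in got.entries] == [d for d, _ in expected]
        for (_, s_got, _), (_, s_exp) in zip(got.entries, expected):
            assert s_got == pytest.approx(s_exp, abs=1e-9)


def test_ranker_params_validation():
    with pytest.raises(ValueError):
        RankerParams(method="tfidf")
    with pytest.raises(ValueError):
        RankerParams(method="dfr", c=0.0)
    with pytest.raises(ValueError):
        RankerParams(b=1.5)
    with pytest.raises(ValueError):
        RankerParams(field_weights={"a": 0.0, "b": 0.0})
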