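"""RM3 expansion: hand-worked relevance models, distribution
contracts and the alpha=1 degeneration."""

import pytest

from bioir.corpus import FieldedDocument, build_index
from bioir.ranking import RankerParams, WeightedQuery, search
from bioir.rm3 import (
    PseudoCollection,
    RM3Params,
    estimate_relevance_model,
    interpolate_and_truncate,
    pseudo_collection,
    rm3_expand,
    smoothed_doc_model,
)


def _pc(entries):
    return PseudoCollection(entries=entries)


def test_smoothed_doc_model_unsmoothed():
    """mu=0 reduces to the maximum-likelihood document model."""
    entry = ("D1", 2.0, ["a", "a", "b"] + ["c"] * 7)
    pc = _pc([entry])
    assert smoothed_doc_model("a", entry, pc, mu=0.0) == pytest.approx(0.2)


def test_smoothed_doc_model_absent_term_zero():
    entry = ("D1", 1.0, ["a", "b"])
    pc = _pc([entry])
    assert smoothed_doc_model("z", entry, pc, mu=50.0) == 0.0


def test_smoothed_doc_model_hand_values():
    """mu=100: P(t|D) = (f + mu * f_R/|D_R|) / (|D| + mu)."""
    e1 = ("D1", 2.0, ["a", "a", "b", "c"])
    e2 = ("D2", 1.0, ["a", "d"])
    pc = _pc([e1, e2])
    # f(a,D1)=2, f(a,D_R)=3, |D_R|=6, |D1|=4
    expected = (2 + 100 * 3 / 6) / (4 + 100)
    assert smoothed_doc_model("a", e1, pc, mu=100.0) == pytest.approx(expected, abs=1e-12)


def test_relevance_model_single_doc_is_term_distribution():
    """With one feedback document and mu=0 the score weight cancels in
    the normalization, leaving the document's term distribution."""
    entry = ("D1", 7.3, ["a", "a", "b", "c"])
    rm = estimate_relevance_model(_pc([entry]), mu=0.0)
    assert rm.probs["a"] == pytest.approx(0.5)
    assert rm.probs["b"] == pytest.approx(0.25)
    assert rm.probs["c"] == pytest.approx(0.25)


def test_relevance_model_two_doc_hand_computation():
    """Two feedback documents with scores 2.0 and 1.0, mu=0: the model
    mass of each term is sum_D P(t|D) * r(D,Q), then normalized."""
    e1 = ("D1", 2.0, ["a", "a", "b", "c"])
    e2 = ("D2", 1.0, ["a", "d"])
    rm = estimate_relevance_model(_pc([e1, e2]), mu=0.0)
    raw = {
        "a": 0.5 * 2.0 + 0.5 * 1.0,   # 1.5
        "b": 0.25 * 2.0,              # 0.5
        "c": 0.25 * 2.0,              # 0.5
        "d": 0.5 * 1.0,               # 0.5
    }
    total = sum(raw.values())         # 3.0
    for term, mass in raw.items():
        assert rm.probs[term] == pytest.approx(mass / total, abs=1e-9)
    assert sum(rm.probs.values()) == pytest.approx(1.0, abs=1e-9)


def test_relevance_model_two_doc_smoothed_hand_computation():
    """Same pseudo-collection with mu=10, verified against explicit
    arithmetic of the smoothed estimates."""
    e1 = ("D1", 2.0, ["a", "a", "b", "c"])
    e2 = ("D2", 1.0, ["a", "d"])
    pc = _pc([e1, e2])
    mu = 10.0
    terms = ["a", "b", "c", "d"]
    tf = {("D1", "a"): 2, ("D1", "b"): 1, ("D1", "c"): 1, ("D2", "a"): 1,
          ("D2", "d"): 1}
    coll_tf = {"a": 3, "b": 1, "c": 1, "d": 1}
    raw = {}
    for t in terms:
        mass = 0.0
        for doc, score, dl in (("D1", 2.0, 4), ("D2", 1.0, 2)):
            p = (tf.get((doc, t), 0) + mu * coll_tf[t] / 6) / (dl + mu)
            mass += p * score
        raw[t] = mass
    total = sum(raw.values())
    rm = estimate_relevance_model(pc, mu=mu)
    for t in terms:
        assert rm.probs[t] == pytest.approx(raw[t] / total, abs=1e-9)


def test_interpolation_alpha_one_returns_normalized_query():
    rm_probs = {"x": 0.6, "y": 0.4}
    from bioir.rm3 import RelevanceModel
    query = WeightedQuery({"a": 2.0, "b": 1.0})
    out = interpolate_and_truncate(RelevanceModel(rm_probs), query,
                                   alpha=1.0, m=5)
    assert out.weights == pytest.approx({"a": 2 / 3, "b": 1 / 3})


def test_interpolation_alpha_zero_returns_truncated_model():
    from bioir.rm3 import RelevanceModel
    rm = RelevanceModel({"x": 0.6, "y": 0.4})
    query = WeightedQuery({"a": 1.0})
    out = interpolate_and_truncate(rm, query, alpha=0.0, m=5)
    assert out.weights == pytest.approx({"x": 0.6, "y": 0.4})


def test_truncation_keeps_m_highest_with_lexicographic_ties():
    from bioir.rm3 import RelevanceModel
    rm = RelevanceModel({"b": 0.3, "a": 0.3, "c": 0.4})
    query = WeightedQuery({"q": 1.0})
    out = interpolate_and_truncate(rm, query, alpha=0.0, m=2)
    # ties at 0.3 resolved lexicographically: keep c (0.4) and a
    assert set(out.weights) == {"c", "a"}
    assert out.weights["c"] == pytest.approx(0.4 / 0.7)


def test_expanded_weights_form_distribution(fixture_index):
    query = WeightedQuery({"q000w0": 1.0, "q000w1": 1.0})
    ranker = RankerParams(field_weights={"abstract": 1.0, "title": 1.0})
    params = RM3Params(alpha=0.3, mu=100.0, k=3, m=8, rm_field="abstract")
    out = rm3_expand(query, fixture_index, ranker, params)
    assert sum(out.weights.values()) == pytest.approx(1.0, abs=1e-9)
    assert len(out.support) > len(query.support)
    assert len(out.support) <= params.m + len(query.support)


def test_pseudo_collection_consistent_with_search(fixture_index):
    query = WeightedQuery({"q001w0": 1.0})
    ranker = RankerParams(field_weights={"abstract": 1.0, "title": 1.0})
    params = RM3Params(k=3, rm_field="abstract")
    pc = pseudo_collection(query, fixture_index, ranker, params)
    top = search(query, fixture_index, ranker).entries[:3]
    assert [(d, s) for d, s, _ in pc.entries] == \
           [(d, s) for d, s, _ in top]
    assert pc.total_length == sum(len(t) for _, _, t in pc.entries)
    recount = {}
    for _, _, terms in pc.entries:
        for t in terms:
            recount[t] = recount.get(t, 0) + 1
    assert pc.collection_tf == recount


def test_alpha_one_preserves_ranking_order(fixture_index):
    """With alpha=1 the expanded query is the normalized original, so
    the final ordering is identical to the unexpanded ranking."""
    query = WeightedQuery({"q002w0": 1.0, "q002w1": 1.0, "t000003": 1.0})
    ranker = RankerParams(field_weights={"abstract": 1.0, "title": 1.0})
    base = search(query, fixture_index, ranker)
    expanded = rm3_expand(query, fixture_index, ranker,
                          RM3Params(alpha=1.0, k=3, m=8, rm_field="abstract"))
    after = search(expanded, fixture_index, ranker)
    assert after.doc_ids() == base.doc_ids()


def test_fallback_on_zero_matches(fixture_index, caplog):
    query = WeightedQuery({"zzzznotaterm": 1.0})
    ranker = RankerParams(field_weights={"abstract": 1.0})
    out = rm3_expand(query, fixture_index, ranker, RM3Params())
    assert out.weights == query.weights


def test_paper_parameterisation_runs(fixture_index):
    """alpha=0.3, k=3, m=8, mu=100 with the abstract field enlarges the
    query support without error."""
    query = WeightedQuery({"q004w0": 1.0, "q004w1": 1.0})
    ranker = RankerParams(field_weights={"abstract": 1.0, "title": 1.0})
    out = rm3_expand(query, fixture_index, ranker,
                     RM3Params(alpha=0.3, k=3, m=8, mu=100.0,
                               rm_field="abstract"))
    assert len(out.support) > len(query.support)


def test_end_to_end_equals_step_composition(fixture_index):
    query = WeightedQuery({"q005w0": 1.0, "q005w1": 2.0})
    ranker = RankerParams(field_weights={"abstract": 1.0, "title": 1.0})
    params = RM3Params(alpha=0.4, mu=50.0, k=4, m=6, rm_field="abstract")
    pc = pseudo_collection(query, fixture_index, ranker, params)
    rm = estimate_relevance_model(pc, params.mu)
    manual = interpolate_and_truncate(rm, query, params.alpha, params.m)
    auto = rm3_expand(query, fixture_index, ranker, params)
    assert auto.weights == pytest.approx(manual.weights)


def test_rm3_params_validation():
    with pytest.raises(ValueError):
        RM3Params(alpha=1.5)
    with pytest.raises(ValueError):
        RM3Params(mu=-1.0)
    with pytest.raises(ValueError):
        RM3Params(k=0)
    with pytest.raises(ValueError):
        RM3Params(m=0)
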