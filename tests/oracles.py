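"""Independent brute-force oracles for cross-checking the library.

Everything here is computed from first principles on raw documents and
run rows — no inverted index, no shared scoring helpers — so that
agreement with the library is a genuine dual-route check: statistics
by full re-scan, ranking by exhaustive per-document evaluation of the
scoring formulas, and evaluation metrics directly from their
definitions.
"""

from __future__ import annotations

import math
from collections import Counter

from bioir.analysis import analyze


def field_term_lists(docs, analyzer, field):
    """doc_id -> analyzed token list for one field (non-empty only)."""
    out = {}
    for doc in docs:
        terms = analyze(doc.fields.get(field, ""), analyzer)
        if terms:
            out[doc.doc_id] = terms
    return out


def brute_force_stats(docs, analyzer, field):
    """Full re-scan statistics: (N, avgdl, df, doc_len, tf) where tf is
    {(doc_id, term): count}."""
    lists = field_term_lists(docs, analyzer, field)
    doc_len = {d: len(t) for d, t in lists.items()}
    df = Counter()
    tf = {}
    for d, terms in lists.items():
        counts = Counter(terms)
        for term, n in counts.items():
            df[term] += 1
            tf[(d, term)] = n
    n_docs = len(lists)
    avgdl = sum(doc_len.values()) / n_docs if n_docs else 0.0
    return n_docs, avgdl, dict(df), doc_len, tf


def _bm25_doc_score(weights, counts, dl, n_docs, avgdl, df, k1, b):
    score = 0.0
    for term, w in weights.items():
        f = counts.get(term, 0)
        n_t = df.get(term, 0)
        if f == 0 or n_t == 0:
            continue
        idf = (n_docs - n_t + 0.5) / (n_t + 0.5)
        score += w * idf * f * (k1 + 1) / (f + k1 * (1 - b + b * dl / avgdl))
    return score


def _dfr_doc_score(weights, counts, dl, n_docs, avgdl, df, c):
    supp = len(weights)
    score = 0.0
    for term, w in weights.items():
        f = counts.get(term, 0)
        n_t = df.get(term, 0)
        if f == 0 or n_t == 0:
            continue
        fprime = f * math.log2(1 + c * avgdl / dl)
        info = math.log2((n_docs + 1) / (n_t + 0.5))
        score += w * (1 / supp) * (fprime / (fprime + 1)) * info
    return score


def brute_force_search(docs, analyzer, weights, method, field_weights,
                       k1=1.2, b=0.75, c=1.0, depth=1000):
    """Score every document exhaustively: per field, weight the field
    score, take the max, keep positives, stable-sort."""
    per_field = {}
    for field, fw in field_weights.items():
        if fw <= 0:
            continue
        n_docs, avgdl, df, doc_len, _tf = brute_force_stats(docs, analyzer, field)
        lists = field_term_lists(docs, analyzer, field)
        per_field[field] = (fw, n_docs, avgdl, df, lists)
    results = []
    for doc in docs:
        best = 0.0
        for field, (fw, n_docs, avgdl, df, lists) in per_field.items():
            terms = lists.get(doc.doc_id)
            if not terms or n_docs == 0:
                continue
            counts = Counter(terms)
            dl = len(terms)
            if method == "bm25":
                s = _bm25_doc_score(weights, counts, dl, n_docs, avgdl, df, k1, b)
            else:
                s = _dfr_doc_score(weights, counts, dl, n_docs, avgdl, df, c)
            best = max(best, fw * s)
        if best > 0:
            results.append((doc.doc_id, best))
    results.sort(key=lambda p: (-p[1], p[0]))
    return results[:depth]


def oracle_evaluate(run_rows, qrels):
    """Evaluation metrics straight from their definitions.

    run_rows: iterable of (topic, doc, rank, score); qrels: topic ->
    {doc: grade}.  Returns topic -> (P10, RPrec, RR) for topics with at
    least one relevant document, with absent topics scored 0.
    """
    by_topic = {}
    for topic, doc, rank, _score in run_rows:
        by_topic.setdefault(topic, []).append((rank, doc))
    out = {}
    for topic, judged in qrels.items():
        relevant = {d for d, g in judged.items() if g > 0}
        if not relevant:
            continue
        ranked = [d for _r, d in sorted(by_topic.get(topic, []))]
        p10 = len([d for d in ranked[:10] if d in relevant]) / 10
        rel = len(relevant)
        rprec = len([d for d in ranked[:rel] if d in relevant]) / rel
        rr = 0.0
        for pos, d in enumerate(ranked, 1):
            if d in relevant:
                rr = 1.0 / pos
                break
        out[topic] = (p10, rprec, rr)
    return out
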