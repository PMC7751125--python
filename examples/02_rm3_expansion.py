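"""Expand a query with RM3 pseudo-relevance feedback.

Generates a synthetic planted collection, expands a two-term query
from its top-3 retrieved documents and prints the expanded term
distribution: the original terms keep alpha of the mass and feedback
terms share the rest.
"""

from bioir import (
    AnalyzerConfig,
    FixtureSpec,
    RankerParams,
    RM3Params,
    WeightedQuery,
    build_index,
    generate_collection,
    rm3_expand,
    search,
)

analyzer = AnalyzerConfig()
coll = generate_collection(FixtureSpec(n_docs=200, n_topics=5,
                                       n_relevant_per_topic=8, seed=4))
index = build_index(coll.documents, analyzer, ["title", "abstract"])
ranker = RankerParams(field_weights={"title": 1.0, "abstract": 1.0})

query = WeightedQuery({"q000w0": 1.0, "q000w1": 1.0})
params = RM3Params(alpha=0.3, mu=100.0, k=3, m=8, rm_field="abstract")
expanded = rm3_expand(query, index, ranker, params)

print(f"original terms: {sorted(query.support)}")
print(f"expanded to {len(expanded.support)} terms "
      f"(weights sum to {sum(expanded.weights.values()):.6f}):")
for term, weight in sorted(expanded.weights.items(), key=lambda kv: -kv[1]):
    marker = "*" if term in query.support else " "
    print(f"  {marker} {term:12s} {weight:.4f}")
print("(* = original query term; alpha=0.3 of the mass stays on them)")

before = search(query, index, ranker).doc_ids()[:5]
after = search(expanded, index, ranker).doc_ids()[:5]
print(f"\ntop 5 before expansion: {before}")
print(f"top 5 after  expansion: {after}")
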