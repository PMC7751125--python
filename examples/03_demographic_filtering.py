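"""Filter clinical-trial results by patient age and gender.

A precision-medicine topic carries a demographic like "38-year-old
male"; trials carry eligibility bounds.  Strict boolean matching
removes trials the patient cannot enrol in, preserving the order of
the survivors.
"""

from bioir import (
    AnalyzerConfig,
    FixtureSpec,
    RankerParams,
    WeightedQuery,
    apply_demographic_filter,
    build_index,
    generate_collection,
    parse_demographic,
    search,
)

analyzer = AnalyzerConfig()
coll = generate_collection(FixtureSpec(n_docs=500, n_topics=3,
                                       n_relevant_per_topic=25,
                                       clinical=True, seed=9))
index = build_index(coll.documents, analyzer, ["title", "abstract"])
params = RankerParams(field_weights={"title": 1.0, "abstract": 1.0})

profile = parse_demographic("38-year-old male")
print(f"patient profile: age={profile.age}, gender={profile.gender}")

query = WeightedQuery({"q000w0": 1.0, "q000w1": 1.0})
unfiltered = search(query, index, params)
filtered = search(query, index, params,
                  doc_filter=apply_demographic_filter(profile, index))
print(f"retrieved trials: {len(unfiltered.entries)} unfiltered, "
      f"{len(filtered.entries)} after eligibility filtering")

for doc_id, score, rank in filtered.entries[:5]:
    doc = index.documents[doc_id]
    print(f"  {rank}. {doc_id}  ages [{doc.min_age}, {doc.max_age}] "
          f"gender={doc.gender}  score={score:.3f}")
# every surviving trial accepts a 38-year-old male: age within the
# bounds (missing bound = unconstrained) and gender male or all
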