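"""Per-task query formulation and the rule-based rewrites.

Shows the default strategies (precision-medicine "disease gene", CDS
summaries), the weighted user-query dialect, topic-field boosting and
the "solid tumor" expansion for non-blood cancers.
"""

from bioir import (
    Topic,
    boost_topic_fields,
    cds_taskB_formulate,
    default_query,
    parse_user_query,
    solid_tumor_expand,
)

pm_topic = Topic("7", {"disease": "melanoma", "gene": "BRAF (V600E)",
                       "demographic": "64-year-old male"})
print("PM default query:  ", default_query(pm_topic, "pm").raw_text)

boosted = boost_topic_fields(pm_topic, w_gene=0.3, w_disease=0.7)
print("field-boosted query:", boosted.fields["user_query"])

expanded = solid_tumor_expand(pm_topic, weight=0.2)
print("solid-tumor expand: ", expanded.fields["user_query"])

leukemia = Topic("8", {"disease": "acute leukemia", "gene": "FLT3"})
print("leukemia unchanged: ",
      solid_tumor_expand(leukemia).fields.get("user_query", "(no expansion)"))

cds_topic = Topic("4", {"type": "test",
                        "summary": "32 year old female with positive HPV screening",
                        "diagnosis": "HPV infection"})
for strategy in ("summary", "diagnosis_objective", "all"):
    print(f"CDS task-B [{strategy}]:",
          cds_taskB_formulate(cds_topic, strategy).raw_text)

spec = parse_user_query("(melanoma)^0.7 (BRAF (V600E))^0.3 (solid tumor)^0.2")
print("\nparsed user query groups (text, weight):")
for text, weight in spec.groups:
    print(f"  {text!r} ^ {weight}")
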