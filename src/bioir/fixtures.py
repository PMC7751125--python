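"""Deterministic synthetic corpus / topic / qrels generation.

The generator emulates the shape of an ad hoc retrieval test
collection at desk scale: documents with Zipf-distributed background
vocabulary in each configured field, topics whose query terms are
planted into a known set of relevant documents, graded qrels marking
those documents relevant, and (for the clinical-trials variant) random
age/gender eligibility constraints plus a patient demographic per
topic.

Topic terms are synthetic tokens ("q003w1") disjoint from the
background vocabulary ("t000123"), so relevance is fully controlled:
the ``relevant_term_overlap`` fraction of each topic's terms is
planted into its relevant documents and the remaining topic terms
occur nowhere in the corpus.  At overlap 0 a topic retrieves nothing;
at overlap 1 every retrieved document is relevant by construction.
All randomness flows from a single integer seed; identical spec and
seed give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .corpus import FieldedDocument, write_corpus_jsonl
from .evaluation import Qrels, write_qrels
from .topics import Topic, write_topics

__all__ = ["FixtureSpec", "FixtureCollection", "generate_corpus",
           "generate_topics_qrels", "generate_collection"]

_TERMS_PER_TOPIC = 5


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic collection.

    fields maps field name -> mean analyzed length (term count drawn
    Poisson around it).  ``relevant_term_overlap`` is the fraction of a
    topic's terms planted into its relevant documents.  ``clinical``
    additionally draws eligibility constraints per document and a
    demographic per topic.
    """

    n_docs: int = 200
    fields: dict[str, float] = dc_field(
        default_factory=lambda: {"title": 8.0, "abstract": 60.0}
    )
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    n_topics: int = 10
    n_relevant_per_topic: int = 5
    relevant_term_overlap: float = 1.0
    clinical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0 or self.n_topics < 0 or self.n_relevant_per_topic < 0:
            raise ValueError("counts must be nonnegative")
        if not 0 <= self.relevant_term_overlap <= 1:
            raise ValueError("relevant_term_overlap must lie in [0, 1]")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be positive")


@dataclass
class FixtureCollection:
    """The in-memory result: documents, topics, qrels and the planted
    ground truth (topic_id -> relevant doc_ids)."""

    documents: list[FieldedDocument]
    topics: list[Topic]
    qrels: Qrels
    planted: dict[str, list[str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write corpus.jsonl, topics.xml and qrels.txt under outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": outdir / "corpus.jsonl",
            "topics": outdir / "topics.xml",
            "qrels": outdir / "qrels.txt",
        }
        write_corpus_jsonl(self.documents, paths["corpus"])
        write_topics(self.topics, paths["topics"])
        write_qrels(self.qrels, paths["qrels"])
        return paths


def _topic_terms(topic_idx: int) -> list[str]:
    return [f"q{topic_idx:03d}w{j}" for j in range(_TERMS_PER_TOPIC)]


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def _plan(spec: FixtureSpec) -> dict[str, list[int]]:
    """Assign each topic its relevant document indices (disjoint
    across topics, deterministic)."""
    planted: dict[str, list[int]] = {}
    cursor = 0
    for i in range(spec.n_topics):
        topic_id = str(i + 1)
        docs = list(range(cursor, min(cursor + spec.n_relevant_per_topic,
                                      spec.n_docs)))
        planted[topic_id] = docs
        cursor += spec.n_relevant_per_topic
    return planted


def generate_corpus(spec: FixtureSpec) -> tuple[list[FieldedDocument], dict[str, list[str]]]:
    """Generate the documents and the planted-relevance sidecar.

    Returns (documents, ground_truth) with ground_truth mapping
    topic_id -> list of planted relevant doc_ids.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _zipf_probs(spec.vocab_size, spec.zipf_exponent)
    plan = _plan(spec)
    n_planted_terms = round(spec.relevant_term_overlap * _TERMS_PER_TOPIC)
    doc_topic: dict[int, str] = {}
    for topic_id, doc_idxs in plan.items():
        for d in doc_idxs:
            doc_topic[d] = topic_id

    docs: list[FieldedDocument] = []
    field_names = list(spec.fields)
    for d in range(spec.n_docs):
        fields: dict[str, str] = {}
        for name in field_names:
            mean_len = spec.fields[name]
            length = max(1, int(rng.poisson(mean_len)))
            idx = rng.choice(spec.vocab_size, size=length, p=probs)
            tokens = [f"t{k:06d}" for k in idx]
            fields[name] = " ".join(tokens)
        topic_id = doc_topic.get(d)
        if topic_id is not None and n_planted_terms > 0:
            terms = _topic_terms(int(topic_id) - 1)[:n_planted_terms]
            # plant into every configured field so any searched field
            # carries the signal
            for name in field_names:
                fields[name] = fields[name] + " " + " ".join(terms)
        kwargs: dict = {}
        if spec.clinical:
            if rng.random() < 0.7:
                lo = int(rng.integers(0, 60))
                kwargs["min_age"] = lo
                kwargs["max_age"] = int(rng.integers(lo, 100))
            kwargs["gender"] = str(rng.choice(["male", "female", "all"]))
        docs.append(
            FieldedDocument(doc_id=f"D{d:05d}", fields=fields, **kwargs)
        )
    ground_truth = {
        topic_id: [f"D{d:05d}" for d in doc_idxs]
        for topic_id, doc_idxs in plan.items()
    }
    return docs, ground_truth


def generate_topics_qrels(
    spec: FixtureSpec, ground_truth: dict[str, list[str]]
) -> tuple[list[Topic], Qrels]:
    """Emit topics and qrels consistent with the planted corpus.

    Each topic's disease/gene fields split its term list so the
    precision-medicine default strategy ("disease gene") reproduces
    exactly the planted query terms.  Qrels mark planted documents
    grade 1 and sample unjudged-irrelevant documents at grade 0.
    """
    rng = np.random.default_rng(spec.seed + 1)
    topics: list[Topic] = []
    qrels = Qrels()
    for i in range(spec.n_topics):
        topic_id = str(i + 1)
        terms = _topic_terms(i)
        half = len(terms) // 2
        fields = {
            "disease": " ".join(terms[:half]),
            "gene": " ".join(terms[half:]),
        }
        if spec.clinical:
            age = int(rng.integers(1, 100))
            gender = str(rng.choice(["male", "female"]))
            fields["demographic"] = f"{age}-year-old {gender}"
        topics.append(Topic(topic_id=topic_id, fields=fields))
        judgements = qrels.judgements.setdefault(topic_id, {})
        for doc_id in ground_truth.get(topic_id, []):
            judgements[doc_id] = 1
        # a few explicit grade-0 judgements, as real qrels pools have
        n_zero = min(5, spec.n_docs)
        if n_zero > 0 and spec.n_docs > 0:
            zeros = rng.choice(spec.n_docs, size=n_zero, replace=False)
            for d in zeros:
                doc_id = f"D{int(d):05d}"
                judgements.setdefault(doc_id, 0)
    return topics, qrels


def generate_collection(spec: FixtureSpec) -> FixtureCollection:
    """Generate documents, topics and qrels in one deterministic pass."""
    docs, ground_truth = generate_corpus(spec)
    topics, qrels = generate_topics_qrels(spec, ground_truth)
    return FixtureCollection(
        documents=docs, topics=topics, qrels=qrels, planted=ground_truth
    )
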