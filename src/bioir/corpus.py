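"""Corpus ingestion and the fielded inverted index.

Documents arrive in a canonical JSON-lines dialect: one object per
line with ``{"id": str, "fields": {name: text, ...}, "min_age": int?,
"max_age": int?, "gender": "male"|"female"|"all"?}``.  The index keeps
per-field postings and the statistics every ranking formula needs:
document count N, document frequencies n_t, average analyzed length
avgdl and per-document lengths |D| — all computed *per field*, over the
documents whose analyzed field is non-empty, so each field defines its
own retrieval space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator

from .analysis import AnalyzerConfig, analyze

__all__ = [
    "FieldedDocument",
    "FieldStatistics",
    "InvertedIndex",
    "build_index",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]

logger = logging.getLogger(__name__)

_GENDERS = {"male", "female", "all"}

_INDEX_FORMAT_VERSION = 1


@dataclass
class FieldedDocument:
    """A document id plus named text fields and optional clinical-trial
    eligibility constraints (age bounds in years, accepted gender)."""

    doc_id: str
    fields: dict[str, str]
    min_age: int | None = None
    max_age: int | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.gender is not None and self.gender not in _GENDERS:
            raise ValueError(f"gender must be one of {_GENDERS}, got {self.gender!r}")
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError(
                f"doc {self.doc_id}: min_age {self.min_age} > max_age {self.max_age}"
            )

    def to_json(self) -> str:
        obj: dict = {"id": self.doc_id, "fields": self.fields}
        if self.min_age is not None:
            obj["min_age"] = self.min_age
        if self.max_age is not None:
            obj["max_age"] = self.max_age
        if self.gender is not None:
            obj["gender"] = self.gender
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "FieldedDocument":
        obj = json.loads(line)
        return cls(
            doc_id=obj["id"],
            fields=dict(obj.get("fields", {})),
            min_age=obj.get("min_age"),
            max_age=obj.get("max_age"),
            gender=obj.get("gender"),
        )


def read_corpus_jsonl(path: str | Path) -> Iterator[FieldedDocument]:
    """Stream documents from a canonical JSONL corpus file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                yield FieldedDocument.from_json(line)
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed corpus line: {exc}")


def write_corpus_jsonl(docs: Iterable[FieldedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(doc.to_json() + "\n")


@dataclass
class FieldStatistics:
    """Per-field corpus statistics.

    ``n_docs`` (N) counts documents whose analyzed field is non-empty;
    ``avgdl`` is the mean analyzed length over those documents; ``df``
    maps term -> number of documents containing it; ``doc_len`` maps
    doc_id -> analyzed length |D|.
    """

    field_name: str
    n_docs: int = 0
    avgdl: float = 0.0
    df: dict[str, int] = dc_field(default_factory=dict)
    doc_len: dict[str, int] = dc_field(default_factory=dict)


class InvertedIndex:
    """In-memory per-field inverted index.

    Postings are ``field -> term -> [(doc_id, tf), ...]`` with lists
    sorted by doc_id.  The raw documents are retained for relevance
    modelling (RM3 pseudo-collections) and result display.
    """

    def __init__(
        self,
        analyzer: AnalyzerConfig,
        schema: list[str],
        aggregate_field: str | None = None,
    ):
        if not schema:
            raise ValueError("schema must name at least one field")
        self.analyzer = analyzer
        self.schema = list(schema)
        self.aggregate_field = aggregate_field
        self.postings: dict[str, dict[str, list[tuple[str, int]]]] = {
            f: {} for f in self.schema
        }
        self.stats: dict[str, FieldStatistics] = {
            f: FieldStatistics(f) for f in self.schema
        }
        self.documents: dict[str, FieldedDocument] = {}

    # -- construction -------------------------------------------------

    def add_document(self, doc: FieldedDocument) -> None:
        if doc.doc_id in self.documents:
            raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
        stored_fields = dict(doc.fields)
        if self.aggregate_field is None:
            # with an aggregate field every text field contributes to it,
            # so "unknown" fields only exist without one
            for name in doc.fields:
                if name not in self.schema:
                    logger.warning(
                        "document %s: field %r not in schema, ignored",
                        doc.doc_id, name,
                    )
        if self.aggregate_field is not None:
            parts = [
                doc.fields[f]
                for f in sorted(doc.fields)
                if f != self.aggregate_field and doc.fields[f]
            ]
            stored_fields[self.aggregate_field] = " ".join(parts)
        stored = FieldedDocument(
            doc_id=doc.doc_id,
            fields=stored_fields,
            min_age=doc.min_age,
            max_age=doc.max_age,
            gender=doc.gender,
        )
        self.documents[doc.doc_id] = stored
        for field_name in self.schema:
            text = stored.fields.get(field_name, "")
            terms = analyze(text, self.analyzer)
            if not terms:
                continue
            st = self.stats[field_name]
            st.doc_len[doc.doc_id] = len(terms)
            counts: dict[str, int] = {}
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
            fp = self.postings[field_name]
            for t, tf in counts.items():
                fp.setdefault(t, []).append((doc.doc_id, tf))
                st.df[t] = st.df.get(t, 0) + 1

    def _finalize(self) -> None:
        for field_name in self.schema:
            for plist in self.postings[field_name].values():
                plist.sort(key=lambda p: p[0])
            st = self.stats[field_name]
            st.n_docs = len(st.doc_len)
            st.avgdl = (
                sum(st.doc_len.values()) / st.n_docs if st.n_docs > 0 else 0.0
            )

    # -- queries ------------------------------------------------------

    def term_frequency(self, field: str, term: str, doc_id: str) -> int:
        """f(t, D) for the analyzed field; 0 when the term is absent."""
        if field not in self.schema:
            raise KeyError(f"unknown field: {field!r}")
        plist = self.postings[field].get(term, [])
        # postings lists are short at desk scale; linear scan is fine
        for d, tf in plist:
            if d == doc_id:
                return tf
        return 0

    def analyzed_field(self, doc_id: str, field: str) -> list[str]:
        """Re-analyze a stored document field with the index analyzer."""
        doc = self.documents[doc_id]
        return analyze(doc.fields.get(field, ""), self.analyzer)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned flat-file dump (JSON)."""
        payload = {
            "format_version": _INDEX_FORMAT_VERSION,
            "analyzer": self.analyzer.to_dict(),
            "schema": self.schema,
            "aggregate_field": self.aggregate_field,
            "documents": [json.loads(d.to_json()) for d in
                          (self.documents[k] for k in sorted(self.documents))],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != _INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index format version: {payload.get('format_version')}"
            )
        analyzer = AnalyzerConfig.from_dict(payload["analyzer"])
        # documents were stored with the aggregate field already
        # materialized, so rebuild without re-aggregating
        index = cls(analyzer, payload["schema"], aggregate_field=None)
        index.aggregate_field = payload["aggregate_field"]
        for obj in payload["documents"]:
            index.add_document(FieldedDocument.from_json(json.dumps(obj)))
        index._finalize()
        return index


def build_index(
    corpus: Iterable[FieldedDocument],
    analyzer: AnalyzerConfig,
    schema: list[str],
    aggregate_field: str | None = None,
) -> InvertedIndex:
    """Build a per-field inverted index over ``corpus``.

    When ``aggregate_field`` is given it is materialized per document
    as the concatenation of all its other text fields (the composite
    "text" field of the clinical-trials schema) and must appear in
    ``schema`` to be searchable.

    Raises on duplicate doc_ids; fields present in a document but
    missing from the schema are ignored with a warning.
    """
    index = InvertedIndex(analyzer, schema, aggregate_field=aggregate_field)
    for doc in corpus:
        index.add_document(doc)
    index._finalize()
    return index
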