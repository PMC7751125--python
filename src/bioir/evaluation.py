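"""TREC-style evaluation: qrels, run files, P@10, R-Prec and RR.

Qrels are graded relevance judgements; a document counts as relevant
iff its grade is strictly positive.  Metrics follow the conventions of
the NIST trec_eval tool: topics with no relevant document are excluded
from averaging, topics judged but absent from the run score 0 on every
metric, and the P@10 divisor stays 10 even when fewer than 10
documents were retrieved.

Run files use the standard 6-column format ``topic Q0 doc rank score
tag`` with scores printed to 6 significant digits.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .ranking import ScoredRanking

__all__ = [
    "Qrels",
    "RunFile",
    "EvalReport",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
    "precision_at_10",
    "r_precision",
    "reciprocal_rank",
    "evaluate_run",
]

logger = logging.getLogger(__name__)

METRICS = ("P10", "RPrec", "RR")


@dataclass
class Qrels:
    """topic_id -> doc_id -> integer grade >= 0."""

    judgements: dict[str, dict[str, int]] = dc_field(default_factory=dict)

    def relevant_docs(self, topic_id: str) -> set[str]:
        return {
            d for d, g in self.judgements.get(topic_id, {}).items() if g > 0
        }

    def topics(self) -> list[str]:
        return list(self.judgements)


@dataclass
class RunFile:
    """Ordered run rows (topic_id, doc_id, rank, score, tag); within a
    topic ranks are contiguous from 1 and scores non-increasing."""

    rows: list[tuple[str, str, int, float, str]]

    def by_topic(self) -> dict[str, list[tuple[str, int, float]]]:
        out: dict[str, list[tuple[str, int, float]]] = {}
        for topic_id, doc_id, rank, score, _tag in self.rows:
            out.setdefault(topic_id, []).append((doc_id, rank, score))
        for rows in out.values():
            rows.sort(key=lambda r: r[1])
        return out


@dataclass
class EvalReport:
    """Per-topic metric values and their macro averages."""

    per_topic: dict[str, dict[str, float]]
    macro: dict[str, float]

    def to_csv(self, path: str | Path) -> None:
        """Per-topic CSV (columns topic_id, P10, RPrec, RR) plus a
        final macro row."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["topic_id", *METRICS])
            for topic_id in sorted(self.per_topic, key=_topic_sort_key):
                vals = self.per_topic[topic_id]
                writer.writerow(
                    [topic_id, *(f"{vals[m]:.4f}" for m in METRICS)]
                )
            writer.writerow(["macro", *(f"{self.macro[m]:.4f}" for m in METRICS)])


def _topic_sort_key(topic_id: str):
    return (0, int(topic_id)) if topic_id.isdigit() else (1, topic_id)


# -- qrels ------------------------------------------------------------


def read_qrels(path: str | Path) -> Qrels:
    """Parse whitespace-separated qrels lines ``topic 0 doc grade``.

    A duplicate (topic, doc) pair keeps the last grade with a warning;
    malformed lines are errors naming the line number.
    """
    qrels = Qrels()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            topic_id, _iter, doc_id, grade_s = parts
            try:
                grade = int(grade_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: grade {grade_s!r} is not an integer")
            if grade < 0:
                raise ValueError(f"{path}:{lineno}: negative grade {grade}")
            topic = qrels.judgements.setdefault(topic_id, {})
            if doc_id in topic:
                logger.warning(
                    "%s:%d: duplicate judgement for (%s, %s); keeping the last",
                    path, lineno, topic_id, doc_id,
                )
            topic[doc_id] = grade
    return qrels


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for topic_id in sorted(qrels.judgements, key=_topic_sort_key):
            for doc_id in sorted(qrels.judgements[topic_id]):
                fh.write(f"{topic_id} 0 {doc_id} {qrels.judgements[topic_id][doc_id]}\n")


# -- run files --------------------------------------------------------


def _format_score(score: float) -> str:
    """6 significant digits, zero-padded (2.5 -> "2.50000")."""
    return np.format_float_positional(
        score, precision=6, unique=False, fractional=False, trim="k"
    )


def write_run(
    rankings: Iterable[ScoredRanking], path: str | Path, tag: str = "bioir"
) -> None:
    """Write rankings as a TREC run file, topics in ascending order,
    single-space separated: ``topic Q0 doc rank score tag``."""
    rankings = sorted(rankings, key=lambda r: _topic_sort_key(r.topic_id))
    with open(path, "w", encoding="utf-8") as fh:
        for ranking in rankings:
            for doc_id, score, rank in ranking.entries:
                fh.write(
                    f"{ranking.topic_id} Q0 {doc_id} {rank} "
                    f"{_format_score(score)} {tag}\n"
                )


def read_run(path: str | Path) -> RunFile:
    rows: list[tuple[str, str, int, float, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            topic_id, _q0, doc_id, rank_s, score_s, tag = parts
            rows.append((topic_id, doc_id, int(rank_s), float(score_s), tag))
    return RunFile(rows=rows)


def run_from_rankings(
    rankings: Iterable[ScoredRanking], tag: str = "bioir"
) -> RunFile:
    rows = []
    for ranking in rankings:
        for doc_id, score, rank in ranking.entries:
            rows.append((ranking.topic_id, doc_id, rank, score, tag))
    return RunFile(rows=rows)


# -- metrics ----------------------------------------------------------


def precision_at_10(
    ranked_docs: list[str], judgements: Mapping[str, int]
) -> float:
    """Fraction of relevant documents among the top 10; the divisor is
    always 10, also for rankings shorter than 10."""
    hits = sum(1 for d in ranked_docs[:10] if judgements.get(d, 0) > 0)
    return hits / 10.0


def r_precision(ranked_docs: list[str], judgements: Mapping[str, int]) -> float:
    """Precision at cutoff rel, where rel is the topic's number of
    relevant documents; requires rel >= 1."""
    rel = sum(1 for g in judgements.values() if g > 0)
    if rel == 0:
        raise ValueError("r_precision undefined for a topic with no relevant document")
    hits = sum(1 for d in ranked_docs[:rel] if judgements.get(d, 0) > 0)
    return hits / rel


def reciprocal_rank(ranked_docs: list[str], judgements: Mapping[str, int]) -> float:
    """1 / rank of the first relevant retrieved document; 0 if none."""
    for i, d in enumerate(ranked_docs, 1):
        if judgements.get(d, 0) > 0:
            return 1.0 / i
    return 0.0


def evaluate_run(run: RunFile, qrels: Qrels) -> EvalReport:
    """Per-topic and macro-averaged P@10, R-Prec and RR.

    Topics are taken from the qrels; those with no relevant document
    are excluded from the report, and judged topics missing from the
    run contribute 0 on all metrics.  Run and qrels must share at
    least one topic.
    """
    run_topics = run.by_topic()
    evaluated = [
        t for t in qrels.topics() if len(qrels.relevant_docs(t)) > 0
    ]
    if not evaluated:
        raise ValueError("qrels contain no topic with a relevant document")
    if not set(run_topics) & set(qrels.topics()):
        raise ValueError("run and qrels share no topics")
    per_topic: dict[str, dict[str, float]] = {}
    for topic_id in evaluated:
        judgements = qrels.judgements[topic_id]
        ranked = [d for d, _rank, _score in run_topics.get(topic_id, [])]
        per_topic[topic_id] = {
            "P10": precision_at_10(ranked, judgements),
            "RPrec": r_precision(ranked, judgements),
            "RR": reciprocal_rank(ranked, judgements),
        }
    macro = {
        m: float(np.mean([v[m] for v in per_topic.values()])) for m in METRICS
    }
    return EvalReport(per_topic=per_topic, macro=macro)
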