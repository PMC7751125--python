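"""End-to-end experiment orchestration.

One experiment = corpus + topics + qrels + a retrieval configuration.
The pipeline mirrors the benchmarking flow: query formulation (per-task
default strategy or user-submitted query), optional RM3 expansion,
search with optional demographic filtering, TREC run-file output and
evaluation.  A serialized configuration plus the input files fully
determine every output, and the configuration is copied into the
output directory so each experiment is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .analysis import AnalyzerConfig
from .corpus import InvertedIndex, build_index, read_corpus_jsonl
from .demographics import apply_demographic_filter, parse_demographic
from .evaluation import EvalReport, evaluate_run, read_qrels, run_from_rankings, write_run
from .ranking import RankerParams, ScoredRanking, search
from .rm3 import RM3Params, rm3_expand
from .topics import (
    Topic,
    default_query,
    parse_user_query,
    query_spec_to_weighted_query,
    read_topics,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Flat, serializable description of one experimental run."""

    corpus: str
    topics: str
    task: str = "pm"
    qrels: str | None = None
    schema: list[str] = dataclasses.field(
        default_factory=lambda: ["title", "abstract"]
    )
    aggregate_field: str | None = None
    ranker: str = "bm25"
    k1: float = 1.2
    b: float = 0.75
    c: float = 1.0
    field_weights: dict[str, float] = dataclasses.field(default_factory=dict)
    depth: int = 1000
    bm25_idf: str = "raw"
    rm3: bool = False
    rm3_alpha: float = 0.3
    rm3_mu: float = 100.0
    rm3_k: int = 3
    rm3_m: int = 8
    rm3_field: str = "abstract"
    demographic_filter: bool = False
    tag: str = "bioir"
    outdir: str = "results"

    def ranker_params(self) -> RankerParams:
        weights = self.field_weights or {f: 1.0 for f in self.schema}
        return RankerParams(
            method=self.ranker,
            k1=self.k1,
            b=self.b,
            c=self.c,
            field_weights=weights,
            depth=self.depth,
            bm25_idf=self.bm25_idf,
        )

    def rm3_params(self) -> RM3Params:
        return RM3Params(
            alpha=self.rm3_alpha,
            mu=self.rm3_mu,
            k=self.rm3_k,
            m=self.rm3_m,
            rm_field=self.rm3_field,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class ExperimentResult:
    run_path: Path
    report_path: Path | None
    query_log_path: Path
    report: EvalReport | None
    rankings: list[ScoredRanking]


def _formulate(topic: Topic, task: str):
    """User-submitted query takes precedence over the task default."""
    user_query = topic.fields.get("user_query")
    if user_query:
        return parse_user_query(user_query)
    return default_query(topic, task)


def run_experiment(
    config: ExperimentConfig,
    analyzer: AnalyzerConfig | None = None,
    index: InvertedIndex | None = None,
) -> ExperimentResult:
    """Execute the full pipeline and write run file, per-topic report
    CSV, query log and the configuration into ``config.outdir``.

    A pre-built ``index`` skips corpus ingestion (it must match the
    configured schema).  Per-topic RM3 fallbacks are warnings; any
    stage failure raises with a stage-named message.
    """
    if analyzer is None:
        analyzer = AnalyzerConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if index is None:
        try:
            index = build_index(
                read_corpus_jsonl(config.corpus),
                analyzer,
                config.schema,
                aggregate_field=config.aggregate_field,
            )
        except Exception as exc:
            raise RuntimeError(f"indexing stage failed: {exc}") from exc
    logger.info("indexing: %d docs in %.2fs", len(index.documents),
                time.perf_counter() - t0)

    try:
        topics = read_topics(config.topics)
    except Exception as exc:
        raise RuntimeError(f"topic-parsing stage failed: {exc}") from exc

    params = config.ranker_params()
    rankings: list[ScoredRanking] = []
    query_log: list[dict] = []
    t0 = time.perf_counter()
    for topic in topics:
        try:
            spec = _formulate(topic, config.task)
            query = query_spec_to_weighted_query(spec, index.analyzer)
        except Exception as exc:
            raise RuntimeError(
                f"query-formulation stage failed for topic {topic.topic_id}: {exc}"
            ) from exc
        if len(query) == 0:
            logger.warning("topic %s: empty query after analysis; skipped",
                           topic.topic_id)
            rankings.append(ScoredRanking(topic_id=topic.topic_id, entries=[]))
            continue
        if config.rm3:
            query = rm3_expand(query, index, params, config.rm3_params())
        doc_filter = None
        if config.demographic_filter:
            profile = parse_demographic(topic.require("demographic"))
            doc_filter = apply_demographic_filter(profile, index)
        try:
            ranking = search(query, index, params, doc_filter=doc_filter,
                             topic_id=topic.topic_id)
        except Exception as exc:
            raise RuntimeError(
                f"search stage failed for topic {topic.topic_id}: {exc}"
            ) from exc
        rankings.append(ranking)
        query_log.append({
            "topic": topic.topic_id,
            "raw_query": spec.raw_text,
            "final_terms": {
                t: round(w, 6)
                for t, w in sorted(query.weights.items())
            },
            "retrieved": len(ranking.entries),
        })
    logger.info("search: %d topics in %.2fs", len(topics),
                time.perf_counter() - t0)

    run_path = outdir / "run.txt"
    write_run(rankings, run_path, tag=config.tag)
    query_log_path = outdir / "queries.json"
    query_log_path.write_text(
        json.dumps(query_log, indent=2, sort_keys=True), encoding="utf-8"
    )
    config.to_json(outdir / "config.json")

    report = None
    report_path = None
    if config.qrels:
        try:
            qrels = read_qrels(config.qrels)
            report = evaluate_run(run_from_rankings(rankings, config.tag), qrels)
        except Exception as exc:
            raise RuntimeError(f"evaluation stage failed: {exc}") from exc
        report_path = outdir / "report.csv"
        report.to_csv(report_path)

    return ExperimentResult(
        run_path=run_path,
        report_path=report_path,
        query_log_path=query_log_path,
        report=report,
        rankings=rankings,
    )
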