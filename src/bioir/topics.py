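"""TREC-style topics and query formulation.

Topics are structured statements of an information need (title / need /
context for the genomics tasks, clinical-case description / summary /
note for the CDS tasks, disease / gene / demographic for the
precision-medicine tasks).  This module parses the generic topic XML
dialect, produces per-task default query strings, parses the minimal
weighted user-query syntax, and implements the rule-based rewrites:
per-field boosting, "solid tumor" expansion for non-blood cancers, and
the composed diagnosis/objective strategies for CDS task B.

The weighted query syntax is deliberately small: whitespace-separated
terms, parenthesized groups, and an optional ``^W`` weight suffix on a
term or group, e.g. ``(melanoma)^0.7 (BRAF (V600E))^0.3``.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

from .analysis import AnalyzerConfig, analyze
from .ranking import WeightedQuery

__all__ = [
    "Topic",
    "QuerySpec",
    "read_topics",
    "write_topics",
    "default_query",
    "parse_user_query",
    "render_query",
    "query_spec_to_weighted_query",
    "boost_topic_fields",
    "solid_tumor_expand",
    "cds_taskB_formulate",
    "TASKS",
]

TASKS = (
    "genomics2004",
    "genomics2005",
    "cds-description",
    "cds-summary",
    "cds-note",
    "pm",
)


@dataclass(frozen=True)
class Topic:
    """A topic id plus named lower-cased text fields."""

    topic_id: str
    fields: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.topic_id:
            raise ValueError("topic_id must be non-empty")
        object.__setattr__(
            self, "fields", {k.lower(): v for k, v in self.fields.items()}
        )

    def require(self, name: str) -> str:
        try:
            return self.fields[name]
        except KeyError:
            raise KeyError(
                f"topic {self.topic_id}: required field {name!r} is missing"
            ) from None

    def with_user_query(self, text: str) -> "Topic":
        fields = dict(self.fields)
        fields["user_query"] = text
        return replace(self, fields=fields)


@dataclass(frozen=True)
class QuerySpec:
    """A query string plus its parse into weighted term groups.

    ``groups`` is a list of (text, weight) pairs; the group text is
    handed verbatim to the analyzer, and the group weight multiplies
    the per-term count weight of every analyzed term in the group.
    ``raw_text`` is the query in the minimal weighted syntax (for task
    strategies that concatenate plain fields it is simply that text).
    """

    raw_text: str
    groups: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for text, weight in self.groups:
            if weight < 0:
                raise ValueError(f"group {text!r}: weight must be nonnegative")


# -- topic files ------------------------------------------------------


def read_topics(path: str | Path) -> list[Topic]:
    """Parse a topic XML file: ``<topics><topic number="..."><FIELD>
    text</FIELD>...</topic></topics>``; field names are lower-cased and
    file order is preserved."""
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed XML at line {exc.position[0]}") from exc
    root = tree.getroot()
    topics: list[Topic] = []
    seen: set[str] = set()
    for el in root.findall("topic"):
        number = el.get("number")
        if not number:
            raise ValueError(f"{path}: <topic> without a number attribute")
        if number in seen:
            raise ValueError(f"{path}: duplicate topic number {number!r}")
        seen.add(number)
        fields = {
            child.tag.lower(): (child.text or "").strip() for child in el
        }
        topics.append(Topic(topic_id=number, fields=fields))
    return topics


def write_topics(topics: list[Topic], path: str | Path) -> None:
    root = ET.Element("topics")
    for t in topics:
        el = ET.SubElement(root, "topic", number=t.topic_id)
        for name, text in t.fields.items():
            ET.SubElement(el, name).text = text
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


# -- default per-task strategies --------------------------------------


def default_query(topic: Topic, task: str) -> QuerySpec:
    """Predefined query formulation per task.

    genomics2004: title + need + context as three groups;
    genomics2005: the narrative field; the CDS variants: the selected
    single field; pm: "disease gene".  All group weights are 1.
    """
    if task == "genomics2004":
        groups = tuple(
            (topic.require(f), 1.0) for f in ("title", "need", "context")
        )
        raw = " ".join(f"({text})" for text, _ in groups)
        return QuerySpec(raw, groups)
    if task == "genomics2005":
        text = topic.require("narrative")
        return QuerySpec(text, ((text, 1.0),))
    if task in ("cds-description", "cds-summary", "cds-note"):
        field = task.split("-", 1)[1]
        text = topic.require(field)
        return QuerySpec(text, ((text, 1.0),))
    if task == "pm":
        text = f"{topic.require('disease')} {topic.require('gene')}"
        return QuerySpec(text, ((text, 1.0),))
    raise ValueError(f"unknown task: {task!r} (expected one of {TASKS})")


# -- the minimal weighted query dialect --------------------------------

_WEIGHT_RE = re.compile(r"^\^(\d+(?:\.\d+)?)$")


def parse_user_query(text: str) -> QuerySpec:
    """Parse the minimal weighted syntax into a QuerySpec.

    Whitespace-separated terms; balanced parenthesized groups (nesting
    inside a group is kept literal); an optional ``^W`` suffix sets the
    term or group weight.  Unbalanced parentheses or malformed weights
    are errors.
    """
    if not text.strip():
        raise ValueError("empty user query")
    groups: list[tuple[str, float]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        if text[i] == "(":
            depth, j = 1, i + 1
            while j < n and depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise ValueError(f"unbalanced parentheses in query: {text!r}")
            group_text = text[i + 1 : j - 1]
            i = j
        elif text[i] == ")":
            raise ValueError(f"unbalanced parentheses in query: {text!r}")
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            token = text[i:j]
            i = j
            if "^" in token:
                term, _, suffix = token.partition("^")
                m = _WEIGHT_RE.match("^" + suffix)
                if not term or m is None:
                    raise ValueError(f"malformed weighted term: {token!r}")
                groups.append((term, float(m.group(1))))
                continue
            group_text = token
            groups.append((group_text, 1.0))
            continue
        # a parenthesized group may carry a ^W suffix
        weight = 1.0
        if i < n and text[i] == "^":
            j = i + 1
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            m = _WEIGHT_RE.match(text[i:j])
            if m is None:
                raise ValueError(f"malformed group weight in query: {text[i:j]!r}")
            weight = float(m.group(1))
            i = j
        groups.append((group_text, weight))
    return QuerySpec(text, tuple(groups))


def _fmt_weight(w: float) -> str:
    return f"{w:g}"


def render_query(spec: QuerySpec) -> str:
    """Render a QuerySpec back to the minimal syntax.

    Canonical form: a single-token group with weight 1 renders bare;
    anything else is parenthesized, with a ``^W`` suffix when the
    weight differs from 1.
    """
    parts = []
    for text, weight in spec.groups:
        bare = " " not in text and "(" not in text and ")" not in text
        if bare and weight == 1.0:
            parts.append(text)
        elif weight == 1.0:
            parts.append(f"({text})")
        else:
            parts.append(f"({text})^{_fmt_weight(weight)}")
    return " ".join(parts)


def query_spec_to_weighted_query(
    spec: QuerySpec, analyzer: AnalyzerConfig | None = None
) -> WeightedQuery:
    """Bridge QuerySpec -> WeightedQuery: every analyzed term of a
    group contributes its count multiplied by the group weight."""
    weights: dict[str, float] = {}
    for text, group_weight in spec.groups:
        if group_weight <= 0:
            continue
        for term in analyze(text, analyzer):
            weights[term] = weights.get(term, 0.0) + group_weight
    return WeightedQuery(weights)


# -- rule-based rewrites (topic field boosting, expansions) ------------


def boost_topic_fields(topic: Topic, w_gene: float, w_disease: float) -> Topic:
    """Attach a user_query boosting the disease and gene topic fields:
    ``(disease)^w_disease (gene)^w_gene``."""
    if w_gene < 0 or w_disease < 0:
        raise ValueError("boost weights must be nonnegative")
    disease = topic.require("disease")
    gene = topic.require("gene")
    query = (
        f"({disease})^{_fmt_weight(w_disease)} ({gene})^{_fmt_weight(w_gene)}"
    )
    return topic.with_user_query(query)


_SOLID_TUMOR_GROUP = "(solid tumor)^"


def solid_tumor_expand(
    topic: Topic,
    weight: float = 0.2,
    skip_ids: set[str] | frozenset[str] = frozenset(),
) -> Topic:
    """Append a down-weighted ``(solid tumor)`` group to the default
    precision-medicine query for non-blood cancers.

    Topics whose disease text contains "leukemia" (case-insensitive)
    and topics in ``skip_ids`` (e.g. non-cancer disorders) are left
    unchanged.  Applying the rewrite twice adds the group only once.
    """
    disease = topic.require("disease")
    if "leukemia" in disease.lower() or topic.topic_id in skip_ids:
        return topic
    existing = topic.fields.get("user_query")
    if existing is not None and _SOLID_TUMOR_GROUP in existing:
        return topic
    base = existing if existing is not None else default_query(topic, "pm").raw_text
    return topic.with_user_query(
        f"{base} (solid tumor)^{_fmt_weight(weight)}"
    )


def cds_taskB_formulate(topic: Topic, strategy: str) -> QuerySpec:
    """Clinical-decision-support task B composition.

    Topics with objective "diagnosis" always use the summary alone;
    other topics follow the chosen strategy: ``summary`` (summary
    only), ``diagnosis_objective`` (known diagnosis plus the objective
    word, e.g. "test"), or ``all`` (summary + objective + diagnosis).
    """
    if strategy not in ("summary", "diagnosis_objective", "all"):
        raise ValueError(f"unknown CDS task B strategy: {strategy!r}")
    summary = topic.require("summary")
    objective = topic.fields.get("type", "").strip()
    if objective.lower() == "diagnosis" or strategy == "summary":
        return QuerySpec(summary, ((summary, 1.0),))
    diagnosis = topic.require("diagnosis")
    if strategy == "diagnosis_objective":
        text = f"{diagnosis} {objective}"
        return QuerySpec(text, ((text, 1.0),))
    text = f"{summary} {objective} {diagnosis}"
    return QuerySpec(text, ((text, 1.0),))
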