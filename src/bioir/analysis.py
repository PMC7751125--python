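"""Text analysis chain: tokenize, case-fold, stopword removal, stemming.

The same :class:`AnalyzerConfig` must be used at indexing and at query
time, otherwise query terms will not line up with the index vocabulary.
The index records its analyzer for exactly this reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .stemming import porter_stem

__all__ = ["AnalyzerConfig", "analyze", "load_stopwords", "DEFAULT_STOPWORDS"]

# The classic 33-word English search-engine stopword list (the Lucene /
# Solr default for English analyzers).
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on
    or such that the their then there these they this to was will
    with""".split()
)

# Maximal runs of unicode alphanumerics; underscore and all punctuation
# (hyphens, parentheses, semicolons, ...) act as separators.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class AnalyzerConfig:
    """Configuration of the analysis chain.

    Parameters
    ----------
    lowercase
        Case-fold tokens before stopword removal and stemming.
    stopwords
        Set of lowercase stopwords to drop.  Entries must be lowercase
        and free of whitespace.
    stemming
        Apply the Porter stemmer to each surviving token.
    """

    lowercase: bool = True
    stopwords: frozenset[str] = field(default=DEFAULT_STOPWORDS)
    stemming: bool = True

    def __post_init__(self) -> None:
        for w in self.stopwords:
            if w != w.lower() or any(c.isspace() for c in w) or not w:
                raise ValueError(
                    f"stopword {w!r} must be lowercase and whitespace-free"
                )
        object.__setattr__(self, "stopwords", frozenset(self.stopwords))

    def to_dict(self) -> dict:
        return {
            "lowercase": self.lowercase,
            "stopwords": sorted(self.stopwords),
            "stemming": self.stemming,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalyzerConfig":
        return cls(
            lowercase=d["lowercase"],
            stopwords=frozenset(d["stopwords"]),
            stemming=d["stemming"],
        )


def analyze(text: str, config: AnalyzerConfig | None = None) -> list[str]:
    """Turn free text into the ordered list of index terms.

    Splits on maximal runs of non-alphanumeric characters, case-folds,
    drops stopwords, then Porter-stems each survivor.  Deterministic;
    empty input yields an empty list.
    """
    if config is None:
        config = AnalyzerConfig()
    tokens = _TOKEN_RE.findall(text)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    tokens = [t for t in tokens if t not in config.stopwords]
    if config.stemming:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword list: one word per line, UTF-8, '#' comments
    and blank lines ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.add(line)
    return frozenset(words)
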