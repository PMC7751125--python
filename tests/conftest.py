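import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bioir.analysis import AnalyzerConfig
from bioir.corpus import FieldedDocument, build_index
from bioir.fixtures import FixtureSpec, generate_collection


@pytest.fixture(scope="session")
def analyzer():
    return AnalyzerConfig()


@pytest.fixture(scope="session")
def small_docs():
    """A tiny hand-readable two-field corpus."""
    return [
        FieldedDocument("D1", {"title": "Ferroportin-1 in humans",
                               "abstract": "iron transport in human cells"}),
        FieldedDocument("D2", {"title": "BRAF mutations in melanoma",
                               "abstract": "the BRAF V600E mutation drives melanoma"}),
        FieldedDocument("D3", {"title": "iron metabolism",
                               "abstract": "iron iron iron homeostasis"}),
        FieldedDocument("D4", {"title": "prostate cancer ATM deletion",
                               "abstract": "ATM loss in prostate tumors"}),
    ]


@pytest.fixture(scope="session")
def small_index(small_docs, analyzer):
    return build_index(small_docs, analyzer, ["title", "abstract"])


@pytest.fixture(scope="session")
def fixture_collection():
    """A 200-document planted collection shared across oracle tests."""
    spec = FixtureSpec(n_docs=200, n_topics=10, n_relevant_per_topic=5,
                       relevant_term_overlap=1.0, seed=42)
    return generate_collection(spec)


@pytest.fixture(scope="session")
def fixture_index(fixture_collection, analyzer):
    return build_index(fixture_collection.documents, analyzer,
                       ["title", "abstract"])
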