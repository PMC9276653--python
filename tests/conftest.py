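import logging

import pytest

from kgforge.corpus import generate_corpus
from kgforge.fixtures import FixtureManifest
from kgforge.graph import GraphStore
from kgforge.pipeline import run_pipeline

logging.getLogger("kgforge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """Default corpus (seed 42) generated once per session."""
    path = tmp_path_factory.mktemp("corpus")
    generate_corpus(FixtureManifest(), path)
    return path


@pytest.fixture(scope="session")
def pipeline_result(corpus_dir):
    """Full prepare -> integrate -> merge -> extract run on the corpus."""
    return run_pipeline(corpus_dir)


@pytest.fixture()
def small_store():
    """Two compounds, a gene and a disease with a few typed edges."""
    store = GraphStore()
    c1 = store.add_node(
        ["Compound", "Chemical"], {"identifier": "DB1", "name": "alpha", "cas": "1-1"}
    )
    c2 = store.add_node(
        ["Compound", "Chemical"], {"identifier": "DB2", "name": "beta"}
    )
    g = store.add_node(["Gene"], {"identifier": "10", "name": "GENEA"})
    d = store.add_node(["Disease"], {"identifier": "MONDO:9", "name": "malady"})
    store.add_edge("TREATS_CHtD", c1, d)
    store.add_edge("BINDS_CHbG", c1, g)
    store.add_edge("INTERACTS_CiC", c1, c2)
    return store
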