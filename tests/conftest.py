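import numpy as np
import pytest
from hypothesis import settings

from latchnet import build_model

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")
from latchnet.patterns import (
    RelationGraph,
    make_lexical_patterns,
    make_semantic_patterns,
)


@pytest.fixture(scope="session")
def graph():
    return RelationGraph.default()


@pytest.fixture(scope="session")
def sem_patterns(graph):
    return make_semantic_patterns(500, 0.06, graph, rng_seed=0)


@pytest.fixture(scope="session")
def lex_patterns():
    return make_lexical_patterns(500, 0.04, 17, rng_seed=1)


@pytest.fixture(scope="session")
def control_model():
    return build_model("control", pattern_seed=0)


@pytest.fixture(scope="session")
def schiz_model(control_model):
    # share the pattern sets so the two conditions differ only in U
    return build_model(
        "schizophrenic",
        sem_patterns=control_model.sem_patterns,
        lex_patterns=control_model.lex_patterns,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
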