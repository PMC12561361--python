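import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpus():
    from neuroscribe.synthetic import letter_corpus

    return letter_corpus()


@pytest.fixture(scope="session")
def library(corpus):
    from neuroscribe.recognition import build_library

    return build_library(corpus)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
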