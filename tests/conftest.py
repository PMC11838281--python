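import pytest
from hypothesis import settings

from pdcm_ner import LabelSet, default_schema

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pdcm_ner.data import ALK_ABSTRACT, EWING_SENTENCE


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def labels(schema):
    return LabelSet.from_schema(schema)


@pytest.fixture(scope="session")
def alk_text():
    """Two-sentence reference abstract with four 'ALK' mentions."""
    return ALK_ABSTRACT


@pytest.fixture(scope="session")
def ewing_sentence():
    return EWING_SENTENCE
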