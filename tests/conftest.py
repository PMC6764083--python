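import pytest
from hypothesis import settings

from frec import (
    AssignmentTable,
    CueConfig,
    english_paradigm,
    italian_paradigm,
)

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture
def table():
    return AssignmentTable()


@pytest.fixture
def english_cue():
    return CueConfig.english()


@pytest.fixture
def italian_cue():
    return CueConfig.italian("H2")


@pytest.fixture
def english():
    return english_paradigm()


@pytest.fixture
def italian():
    return italian_paradigm()
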