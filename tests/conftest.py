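import pytest

from cnvnomen import CMT1_REFERENCE, DGS_REFERENCE, load_table3_fixture
from cnvnomen.scorer import DEFAULT_CONFIG


@pytest.fixture(scope="session")
def table3():
    """The bundled 19-hospital survey fixture and its reference CNVs."""
    submissions, refs = load_table3_fixture()
    return submissions, refs


@pytest.fixture(scope="session")
def refs():
    return DGS_REFERENCE, CMT1_REFERENCE


@pytest.fixture()
def config():
    return DEFAULT_CONFIG
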