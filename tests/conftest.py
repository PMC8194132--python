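import pytest

from alkcea import paper_fixture


@pytest.fixture(scope="session")
def fixture_params():
    """The published parameter set; treated as read-only by tests."""
    return paper_fixture()


@pytest.fixture()
def params(fixture_params):
    """A mutable deep copy of the published parameter set."""
    return fixture_params.model_copy(deep=True)
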