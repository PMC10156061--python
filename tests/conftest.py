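import pytest

from pebpmine.synthetic_data import paper_fixtures


@pytest.fixture(scope="session")
def bundle():
    """The deterministic fixture bundle; treated as read-only by all tests."""
    return paper_fixtures()
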