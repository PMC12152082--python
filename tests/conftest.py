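import pytest

import taxontrace as tt


@pytest.fixture(scope="session")
def fx():
    """The worked-example collections."""
    return tt.fixtures()


@pytest.fixture(scope="session")
def u5():
    return tt.TaxonUniverse.of_size(5)


@pytest.fixture(scope="session")
def u6():
    return tt.TaxonUniverse.of_size(6)


def collection(quads, n):
    return tt.TaxonSetCollection.of_integers(quads, n)
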