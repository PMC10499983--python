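import pytest

from dddnet import build_ddd, builtin_tables, fixture_graphs


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


@pytest.fixture(scope="session")
def tables():
    return builtin_tables()


@pytest.fixture(scope="session")
def ddd_cache():
    """Built DDD(t) graphs shared across tests (construction is pure)."""
    return {t: build_ddd(t) for t in (1, 2, 3)}
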