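import pytest

from smokefree import default_parameters, generate_toy_fixture


@pytest.fixture(scope="session")
def params():
    """Packaged base-case parameter set (shared, read-only by convention)."""
    return default_parameters()


@pytest.fixture()
def fresh_params():
    """A private copy safe to mutate."""
    return default_parameters()


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable 3-state toy instance with closed-form expectations."""
    return generate_toy_fixture()
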