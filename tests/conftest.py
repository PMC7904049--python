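import pytest
from hypothesis import settings

import mi2cast as m

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return m.load_default_registry()


@pytest.fixture(scope="session")
def corpus(registry):
    """Varied valid statements covering every optional field class."""
    return m.gen_corpus(seed=100, n=40, registry=registry)


@pytest.fixture()
def minimal_template():
    return m.generate_template(m.FeatureSelection())
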