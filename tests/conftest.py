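import pytest
from hypothesis import settings

from ditchflux.synthetic_data import GeneratorConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_records():
    """The study-shaped synthetic database at a fixed seed."""
    return generate(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()
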