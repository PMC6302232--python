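import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from infodem.lexicon import lexica_from_mapping
from infodem.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_config():
    return GeneratorConfig(n_users=60, n_messages=400, seed=11)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_config):
    return list(generate_corpus(tiny_config))


@pytest.fixture(scope="session")
def tiny_lexica(tiny_config):
    return lexica_from_mapping(tiny_config.lexicon)
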