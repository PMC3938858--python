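import pytest

from soilhealth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A reduced study region: fast, but structurally complete."""
    return SynthConfig(seed=11, n_zones=40)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """Full-size study region under the default conditions."""
    return generate_study(SynthConfig(seed=7))
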