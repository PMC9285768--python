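import pytest
from hypothesis import HealthCheck, settings

from warmsize.scenarios import (
    NO_INTERACTION,
    SIZE_TEMP_INTERACTION,
    config_template,
    default_parameters,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_on():
    """Calibrated defaults with the size-temperature interaction on."""
    return default_parameters(SIZE_TEMP_INTERACTION)


@pytest.fixture(scope="session")
def params_off():
    return default_parameters(NO_INTERACTION)


@pytest.fixture(scope="session")
def tpl_I_on():
    return config_template("I", SIZE_TEMP_INTERACTION)


@pytest.fixture(scope="session")
def tpl_II_on():
    return config_template("II", SIZE_TEMP_INTERACTION)


@pytest.fixture(scope="session")
def tpl_I_off():
    return config_template("I", NO_INTERACTION)


@pytest.fixture(scope="session")
def tpl_II_off():
    return config_template("II", NO_INTERACTION)
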