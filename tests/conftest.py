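import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import cadecea as cc


@pytest.fixture(scope="session")
def base_config():
    return cc.default_scenario()


@pytest.fixture(scope="session")
def conv_arm(base_config):
    return cc.conventional_detection(base_config.detection)


@pytest.fixture(scope="session")
def cade_arm(base_config):
    return cc.cade_detection(base_config.detection)


@pytest.fixture(scope="session")
def base_results(base_config, conv_arm, cade_arm):
    """Both arms' lifetime cohort runs on the packaged base case."""
    conv = cc.run_arm(base_config, conv_arm)
    cade = cc.run_arm(base_config, cade_arm)
    return conv, cade
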