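import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgfish import ScreeningConfig, default_scenarios, generate_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return ScreeningConfig()


@pytest.fixture(scope="session")
def scenario_pack():
    return default_scenarios()


@pytest.fixture(scope="session")
def study(scenario_pack):
    """Default stratified six-lake survey, fixed seed."""
    return generate_study(scenario_pack, seed=20100315)
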