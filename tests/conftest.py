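import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msbdyn as m

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return m.SceneConfig(seed=7)


@pytest.fixture(scope="session")
def default_scene(default_config):
    return m.generate_scene(default_config)


@pytest.fixture(scope="session")
def default_report(default_config, default_scene):
    """Full scene → render → analysis run, shared across tests."""
    return m.run_pipeline(default_config, default_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
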