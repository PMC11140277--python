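import pytest
from hypothesis import HealthCheck, settings

import trialcea as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark():
    """Deterministic 22-vs-27 reference trial."""
    return tc.benchmark_trial()


@pytest.fixture()
def config():
    """Default analysis config with a small bootstrap for fast tests."""
    return tc.AnalysisConfig(seed=7, bootstrap_B=200)
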