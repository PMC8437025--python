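import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline():
    from coralslab.scenarios import baseline_stack

    return baseline_stack()


@pytest.fixture(scope="session")
def coarse_run(baseline):
    """One small shared pipeline run for solver/metric tests."""
    from coralslab.solvers import run_pipeline

    stack, domain = baseline
    return run_pipeline(stack, domain, n_photons=50_000, seed=11,
                        dz=20e-6, dx=500e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
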