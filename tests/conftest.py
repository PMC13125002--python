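import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crmon.engine import OraclePredictor, run_pipeline
from crmon.simulate import SimulatorConfig, simulate_subject

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject():
    """One default-condition simulated subject (seed 7)."""
    return simulate_subject(SimulatorConfig(), seed=7)


@pytest.fixture(scope="session")
def oracle_series(subject):
    """Pipeline output for the subject under the protocol-oracle predictor."""
    return run_pipeline(subject.ppg, OraclePredictor(subject.reserve_at))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
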