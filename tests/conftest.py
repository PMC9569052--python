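import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import survelicit as sv

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Typical natural-scale parameter points used across family tests.
TYPICAL_PARAMS = {
    "exponential": (0.5,),
    "weibull": (1.3, 0.4),
    "gompertz": (0.2, 0.3),
    "lognormal": (0.2, 0.8),
    "loglogistic": (1.6, 1.5),
    "gamma": (1.4, 0.6),
    "gengamma": (1.2, 0.5, 1.4),
}


@pytest.fixture(scope="session")
def karmma():
    """The packaged trial + consensus fixture emulating the reference study."""
    return sv.karmma_like_fixture(seed=1)


@pytest.fixture(scope="session")
def exp_trial():
    """Simulated exponential single-arm trial, event-rich (>=100 events)."""
    truth = sv.params("exponential", 0.6)
    scenario = sv.TrialScenario(
        truth=truth, n=200, accrual_window=1.0, data_cutoff=4.0, seed=123
    )
    data = sv.simulate_trial(scenario)
    assert data.n_events >= 100
    return data


@pytest.fixture
def tiny_data():
    """Six-subject toy dataset, mixed events and censoring."""
    return sv.IPDDataset(
        times=np.array([0.4, 0.9, 1.1, 1.5, 1.8, 2.0]),
        events=np.array([1, 1, 0, 1, 0, 0]),
    )
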