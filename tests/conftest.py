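import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study_shaped_cohort():
    """A 37-patient table with the 11/19/7 CR/PR/SD split and simple
    survival columns, for arithmetic-level checks."""
    response = ["CR"] * 11 + ["PR"] * 19 + ["SD"] * 7
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "patient_id": [f"P{i:02d}" for i in range(37)],
        "response": response,
        "time_months": rng.uniform(1, 60, 37).round(1),
        "event": rng.random(37) < 0.5,
    })


def random_survival_fixture(rng, n_max=200, censor_frac=0.2, effect=0.0):
    """Random right-censored survival data with a continuous covariate."""
    n = int(rng.integers(20, n_max + 1))
    x = rng.normal(size=n)
    rate = 0.05 * np.exp(effect * x)
    t_event = rng.exponential(1.0 / rate)
    # censoring rate tuned to ~censor_frac censored overall
    t_cens = rng.exponential(1.0 / (0.05 * censor_frac / (1 - censor_frac)), n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return time, event, x
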