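import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trial_config():
    from ergotrial.simulate import load_trial_config

    return load_trial_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_epoch_day(vm_values, start="2016-02-01", steps=None):
    """Build a one-day epoch frame from a vector-magnitude sequence."""
    vm = np.asarray(vm_values, dtype=float)
    n = vm.size
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="m")
    axis1 = np.round(vm * 0.7)
    rest = np.sqrt(np.maximum(vm**2 - axis1**2, 0))
    return pd.DataFrame({
        "timestamp": ts,
        "axis1": axis1.astype(int),
        "axis2": np.round(rest).astype(int),
        "axis3": 0,
        "steps": np.zeros(n, dtype=int) if steps is None else np.asarray(steps),
        "vm": vm,
    })


@pytest.fixture(scope="session")
def epoch_day_factory():
    return make_epoch_day
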