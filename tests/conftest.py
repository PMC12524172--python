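import pytest
from hypothesis import HealthCheck, settings

import opmpipe as op

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 375.0


@pytest.fixture(scope="session")
def small_array():
    """16-sensor (48-channel) triaxial array used by most simulation tests."""
    return op.make_sensor_array(n_sensors=16, seed=0)


@pytest.fixture(scope="session")
def truth():
    return op.default_ground_truth(seed=0, n_regions=14)


@pytest.fixture(scope="session")
def visuomotor_run(small_array, truth):
    """One low-noise visuomotor recording shared across tests (60 trials)."""
    rec, motion = op.simulate_visuomotor_dataset(
        small_array, truth, n_trials=60, seed=11, group="control", snr=5.0)
    return rec, motion
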