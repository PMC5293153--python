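import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eposignal.contexts import make_table1_contexts
from eposignal.network import build_signaling_model, full_topology
from eposignal.synth import default_ground_truth

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def full_model():
    return build_signaling_model(full_topology())


@pytest.fixture(scope="session")
def contexts():
    return {c.name: c for c in make_table1_contexts()}


@pytest.fixture(scope="session")
def truth():
    """Default synthetic ground truth (anchored scales, calibrated links)."""
    return default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def t_grid():
    return np.linspace(0.0, 60.0, 61)
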