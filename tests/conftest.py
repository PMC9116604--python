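import numpy as np
import pytest

from qmtrace import AcquisitionConfig, StateModel, simulate_trace


@pytest.fixture(scope="session")
def two_state_model() -> StateModel:
    """Two-state junction: 100/200 pA levels, 2 ms dwells each."""
    return StateModel.from_bench_units([100.0, 200.0], [2.0, 2.0])


@pytest.fixture(scope="session")
def short_two_state_run(two_state_model):
    """A 10 s filtered, noisy two-state recording plus its ground truth."""
    acq = AcquisitionConfig(
        duration=10.0, noise_sigma=10e-12, bias=-0.1, seed=42
    )
    trace, log = simulate_trace(two_state_model, acq)
    return trace, log, acq


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
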