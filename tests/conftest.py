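import numpy as np
import pytest

from patchbind.channelsim import GatingModel, NoiseModel
from patchbind.sweepio import Protocol


@pytest.fixture
def two_state_09() -> GatingModel:
    """Closed <-> Open, opening 900/s, closing 100/s: stationary P_o 0.9."""
    return GatingModel.two_state(900.0, 100.0)


@pytest.fixture
def step_protocol() -> Protocol:
    """The standard -90/+90/-90 mV step protocol, 700 ms cycle, 20 sweeps."""
    return Protocol(
        segments=((-90.0, 100.0), (90.0, 500.0), (-90.0, 100.0)),
        cycle_period_ms=700.0,
        n_sweeps=20,
        unitary_amplitude_pA={90.0: 10.0, -90.0: -2.5},
    )


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return NoiseModel(baseline_sd=0.0)


@pytest.fixture
def paper_noise() -> NoiseModel:
    return NoiseModel(baseline_sd=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
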