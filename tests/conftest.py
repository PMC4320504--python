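import numpy as np
import pytest

from thermofit import (
    ModelParams,
    Protocol,
    ReferenceSignal,
    TimeGrid,
)
from thermofit.model import simulate_response


@pytest.fixture
def grid30() -> TimeGrid:
    """Standard 30-sample recovery grid (5 min at 0.1 Hz, sample units)."""
    return TimeGrid(n_samples=30, dt=1.0, t0=0.0)


@pytest.fixture
def hc_params() -> ModelParams:
    """Population mean response of the I MCP region in healthy controls:
    slow pole with an undershoot (negative disturbance)."""
    return ModelParams(lag_time=6, pole=0.1, disturbance=-0.07, integral_gain=0.3)


@pytest.fixture
def psa_params() -> ModelParams:
    """Population mean response of the V MCP region in patients: faster
    pole, positive disturbance (no undershoot), strong integral gain."""
    return ModelParams(lag_time=7, pole=0.8, disturbance=0.03, integral_gain=1.5)


@pytest.fixture
def unit_ref() -> ReferenceSignal:
    return ReferenceSignal(T=31.0, y0=30.0)


@pytest.fixture
def protocol() -> Protocol:
    return Protocol()


def make_curve(params: ModelParams, r: float = 1.0, n: int = 30):
    """Noiseless deviation curve from the switched model."""
    return simulate_response(params, r, TimeGrid(n_samples=n))
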