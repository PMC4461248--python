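import numpy as np
import pytest

import pmrflux as pm
from pmrflux.quantify import AcquisitionProtocol

NOISELESS = {"pcr": 0.0, "pi": 0.0, "atp": 0.0, "ph": 0.0}


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def protocol_10s():
    """Fine-binned variant: 10 s stimulation/recovery bins."""
    return AcquisitionProtocol(
        repetition_time_saturated=1.25, rest_packets=(96,),
        stim_packets=(8,) * 36, recovery_packets=(8,) * 96)


@pytest.fixture(scope="session")
def deep_bout():
    """Noiseless fatiguing bout (default, paper-like conditions)."""
    return pm.simulate_bout(pm.SimParams(noise_sd=dict(NOISELESS)))


@pytest.fixture(scope="session")
def mild_bout():
    """Noiseless mild validation bout (estimator-assumption regime)."""
    return pm.simulate_bout(pm.SimParams.validation(noise_sd=dict(NOISELESS)))


@pytest.fixture(scope="session")
def exp_series():
    """Series sampled exactly from the mono-exponential fit models."""
    return pm.exponential_series()


def stim_integral(sim, column="u"):
    """Time integral (umol/g) of a fine-grid column over stimulation."""
    f = sim.fine[sim.fine["phase"] == "stim"]
    return float(np.sum(f[column]) * sim.params.dt_s / 60.0)
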