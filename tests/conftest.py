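import numpy as np
import pytest

from coaflow.patient import generate_synthetic_patient
from coaflow.circuit import default_circuit_params, simulate


@pytest.fixture(scope="session")
def moderate_pre_record():
    return generate_synthetic_patient(3, "moderate", "pre")


@pytest.fixture(scope="session")
def moderate_post_record():
    return generate_synthetic_patient(7, "moderate", "post")


@pytest.fixture(scope="session")
def steady_waves(moderate_pre_record):
    """Steady waveforms of an uncalibrated moderate-COA circuit."""
    params = default_circuit_params(moderate_pre_record)
    return params, simulate(params, n_cycles=80, stop_when_steady=True)
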