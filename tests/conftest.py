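import numpy as np
import pytest

from hyperkin import InputFunction, KineticParameters
from hyperkin.synthetic import (
    generate_timeseries,
    invitro_acquisition,
    invitro_input,
    invitro_kinetics,
    invivo_acquisition,
)


@pytest.fixture(scope="session")
def invitro_acq():
    return invitro_acquisition()


@pytest.fixture(scope="session")
def invivo_acq():
    return invivo_acquisition()


@pytest.fixture(scope="session")
def two_site_params():
    """Typical exchange rates (k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)."""
    return KineticParameters(k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)


@pytest.fixture(scope="session")
def raised_cosine_input():
    return InputFunction.raised_cosine(3.0, onset_s=2.0, duration_s=10.0)


@pytest.fixture(scope="session")
def invitro_record(invitro_acq):
    """Noiseless in vitro style record: pre-grid bolus, 128 pts at TR 2 s."""
    return generate_timeseries(invitro_kinetics(), invitro_input(), invitro_acq)


def decay_horizon(params, margin: float = 32.0) -> float:
    """Time for every mode of the model to decay to ~e**-margin."""
    from hyperkin.simulate import system_matrix

    A, _ = system_matrix(params)
    lam = np.linalg.eigvals(A)
    slowest = np.min(np.abs(lam.real))
    return margin / slowest
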