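import warnings

import numpy as np
import pytest

from cyclescale import oscillator as osc
from cyclescale import periods as per


@pytest.fixture(scope="session")
def ref_params():
    return osc.reference_params()


@pytest.fixture(scope="session")
def fast_sim():
    """Light integration settings for sweeps in tests."""
    return per.SimOptions(t_end=400.0, rtol=1e-6, atol=1e-9, method="LSODA")


@pytest.fixture(scope="session")
def ref_trajectory(ref_params):
    """Reference trajectory at default (production) solver settings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return osc.simulate(ref_params, t_end=1000.0)


@pytest.fixture(scope="session")
def ref_period(ref_trajectory):
    return per.detect_period(ref_trajectory)


@pytest.fixture(autouse=True)
def _silence_extrapolation_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
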