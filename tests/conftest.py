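import numpy as np
import pytest

from neutraldebt import AbundanceSpectrum, LogseriesCommunity, ModelParams


@pytest.fixture(scope="session")
def community():
    """The canonical regional community: omega=0.001, A=100, S0=1000."""
    return LogseriesCommunity(omega=0.001, A=100.0, S0=1000.0)


@pytest.fixture(scope="session")
def toy_spectrum():
    """Hand-checkable two-class spectrum: 10 singletons-of-1, 5 species at 2."""
    return AbundanceSpectrum.from_counts({1: 10.0, 2: 5.0})


@pytest.fixture(scope="session")
def drift_params():
    return ModelParams(u=0.0, v=0.0)


@pytest.fixture(scope="session")
def time_grid_short():
    return np.round(np.arange(0.0, 50.25, 0.25), 6)
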