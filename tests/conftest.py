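"""Shared fixtures: one noiseless phantom reused across test modules."""

import numpy as np
import pytest

from ctaphase.synthetic import BolusParams, PhantomGeometry, simulate_ctp_series


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def noiseless_params():
    return BolusParams(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_params, geometry):
    """(series, truth) of the default bolus with zero noise."""
    return simulate_ctp_series(noiseless_params, geometry)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
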