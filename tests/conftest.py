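"""Shared fixtures: coarse-but-accurate grids and small ensembles."""
import numpy as np
import pytest

from caroteet.spectral_density import carotenoid_sd, retinal_sd


@pytest.fixture(scope="session")
def time_grid_fs():
    """2 ps at 0.25 fs: damps every pigment lineshape used in the tests."""
    return np.arange(0, 8001) * 0.25


@pytest.fixture(scope="session")
def energy_grid_ev():
    return 0.4 + np.arange(1901) * 0.002


@pytest.fixture(scope="session")
def sxn_sd():
    return carotenoid_sd(3593.0, label="SXN")


@pytest.fixture(scope="session")
def lut_sd():
    return carotenoid_sd(1787.0, label="LUT")


@pytest.fixture(scope="session")
def rpsb_sd():
    return retinal_sd(1500.0, label="rPSB")
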