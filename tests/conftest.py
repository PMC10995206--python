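import numpy as np
import pytest

from ulmloc.config import ImagingConfig, SimulationParams
from ulmloc.io import gaussian_bank
from ulmloc.noise import NoiseModel
from ulmloc.templates import TemplateBank, make_gaussian_template


@pytest.fixture(scope="session")
def cam_cfg():
    """CAM-like geometry: 20 MHz, 12.3 um fine pixels, 80x80 fine FOV."""
    return ImagingConfig()


@pytest.fixture(scope="session")
def sim_params():
    return SimulationParams(concentration_per_lambda2=0.05)


@pytest.fixture(scope="session")
def small_bank():
    return gaussian_bank(n=8, side=21, seed=11)


@pytest.fixture(scope="session")
def iso_bank():
    """Single isotropic Gaussian template (sigma = 2 fine px)."""
    return TemplateBank([make_gaussian_template(2.0, 2.0, 21)],
                        mu_imax=1.0, sigma_imax=0.2)


@pytest.fixture(scope="session")
def flat_noise(cam_cfg):
    return NoiseModel.constant(0.1, cam_cfg.fov_input)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
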