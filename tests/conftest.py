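"""Shared fixtures for the thermopose test suite."""

import numpy as np
import pytest

from thermopose.pose import CameraModel, default_head_template
from thermopose.radiometry import RadiometricCalibration
from thermopose.simulate import SimulationConfig, simulate_records


@pytest.fixture(scope="session")
def calib():
    return RadiometricCalibration()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def template():
    return default_head_template()


#: SimulationConfig overrides that remove every systematic effect, leaving
#: pure AR1 noise around the region baselines (used by null-calibration tests).
NULL_EFFECTS = dict(
    decline_eye_C=0.0,
    decline_bill_C=0.0,
    yaw_bias_amplitude_eye_C=0.0,
    indiv_slope_sd_eye_C=0.0,
    indiv_slope_sd_bill_C=0.0,
)


@pytest.fixture(scope="session")
def small_records():
    """Frame-level records from a reduced experiment (4 stress / 3 control)."""
    cfg = SimulationConfig(seed=11, n_stress=4, n_control=3)
    return simulate_records(cfg)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q
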