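import numpy as np
import pytest

from flavanms import REGISTRY_NAMES, SimulationConfig, simulate_calibration

CAL_LEVELS = [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]


@pytest.fixture()
def cfg():
    return SimulationConfig(seed=20230901)


@pytest.fixture()
def quiet_cfg():
    """Noise-free configuration: every area sits exactly on the line."""
    return SimulationConfig(seed=0, cv_injection=0.0, sd_additive=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def calibration_table(cfg):
    return simulate_calibration(CAL_LEVELS, reps=3, cfg=cfg)


@pytest.fixture(params=list(REGISTRY_NAMES))
def compound_name(request):
    return request.param
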