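import numpy as np
import pytest

from drgquant import imsim, quant


@pytest.fixture
def sim_cfg():
    """Default confocal-like simulation settings with detection noise."""
    return imsim.SimulationConfig(seed=0)


@pytest.fixture
def sim_cfg_clean():
    """Noise-free variant for exact renders."""
    return imsim.SimulationConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def quant_cfg():
    return quant.QuantConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
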