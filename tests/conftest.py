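import numpy as np
import pytest

from cmrquant import aha
from cmrquant.perfusion import DeconvConfig
from cmrquant.signal_model import SaturationRecoveryParams


@pytest.fixture
def sr_params():
    return SaturationRecoveryParams(ts=0.1, n_baseline=5)


@pytest.fixture
def deconv_config():
    return DeconvConfig()


@pytest.fixture
def uniform_mbf():
    def make(value):
        return {s: value for s in aha.SEGMENTS}

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
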