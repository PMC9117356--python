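import numpy as np
import pytest

import adctex as at


@pytest.fixture(scope="session")
def default_phantom():
    return at.generate_phantom(at.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """All compartment SDs zero: every voxel equals its compartment mean."""
    adc_cfg = {k: at.CompartmentAdc(v[0], 0.0) for k, v in at.synthetic.DEFAULT_ADC.items()}
    cfg = at.PhantomConfig(adc=adc_cfg, seed=0)
    return at.generate_phantom(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
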