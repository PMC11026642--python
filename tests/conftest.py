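import numpy as np
import pytest

from ecmmech.synthetic import CurveGenSpec, generate_force_curve


@pytest.fixture
def noiseless_spec() -> CurveGenSpec:
    return CurveGenSpec(E_true=470.0, noise_sd=0.0, adhesion_depth=1.02e-9,
                        hysteresis_factor=0.3, seed=0)


@pytest.fixture
def noiseless_curve(noiseless_spec):
    return generate_force_curve(noiseless_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
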