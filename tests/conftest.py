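import numpy as np
import pytest

from depthcue import CueStrengths, MLEParams, Stimulus, VecSumParams


@pytest.fixture
def rng():
    return np.random.default_rng(20230458)


@pytest.fixture
def pythagorean():
    """Texture+shading strengths whose norm is exactly 1 (3-4-5 triple)."""
    return CueStrengths({"texture": 0.6, "shading": 0.8})


@pytest.fixture
def unit_stimulus(pythagorean):
    return Stimulus(10.0, pythagorean)


@pytest.fixture
def vs_params():
    return VecSumParams(sigma_M=1.0)


@pytest.fixture
def mle_params():
    return MLEParams({"texture": 1.0, "shading": 2.0})
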