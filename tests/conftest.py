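import numpy as np
import pytest

from echoray import AttenuationVolume, PhantomSpec, make_phantom
from echoray.volume import Layer


@pytest.fixture
def uniform_volume() -> AttenuationVolume:
    """Homogeneous medium: no interfaces, no attenuation."""
    return AttenuationVolume(np.ones((16, 16, 32)), spacing=(0.5, 0.5, 0.5))


@pytest.fixture
def two_layer_volume() -> AttenuationVolume:
    """delta = 1 above 8 mm depth, 3 below: one planar interface on axis 2."""
    spec = PhantomSpec(
        grid_shape=(16, 16, 32),
        spacing=(0.5, 0.5, 0.5),
        background_delta=1.0,
        layers=(Layer(8.0, 3.0),),
    )
    return make_phantom(spec)


@pytest.fixture
def ramp_volume() -> AttenuationVolume:
    """delta = a*z linear ramp along the depth axis (a = 0.5 per mm).

    101 slices at 0.2 mm spacing span 20 mm of depth with delta 0..10.
    """
    values = np.tile(np.linspace(0.0, 10.0, 101), (8, 8, 1))
    return AttenuationVolume(values, spacing=(1.0, 1.0, 0.2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
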