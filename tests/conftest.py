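import numpy as np
import pytest

from ridgesim import HomogeneousField, make_preset

PRESET_NAMES = ["kc2012", "kc-adapted", "kc-reparam", "piecewise", "oscillator2014"]


@pytest.fixture(params=PRESET_NAMES)
def any_model(request):
    """Each force family at the canonical parameter sets, cutoff 0.5."""
    return make_preset(request.param, cutoff_radius=0.5)


@pytest.fixture
def vertical_field():
    """Homogeneous field with s = (0, 1): the canonical line-pattern frame."""
    return HomogeneousField(np.pi / 2, chi=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
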