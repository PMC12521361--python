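import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tibmorph.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def coarse_phantom():
    """One 10 µm phantom with flat interfaces (landmarks at 0.4/0.5/0.75 mm)."""
    spec = PhantomSpec.coarse(seed=7)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def fine_phantom():
    """The default 5 µm phantom (300×300×420); landmarks at 0.5/0.6/0.9 mm."""
    spec = PhantomSpec(seed=11)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
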