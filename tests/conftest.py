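import numpy as np
import pytest

from cervimetry.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Default straight tube: length 30 mm, canal radius 3 mm, 0.8 mm grid."""
    spec = PhantomSpec()
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def bent_phantom():
    """Bent two-segment tube (90-degree hinge) used by landmark tests."""
    spec = PhantomSpec(
        inlet_point=(0.0, 10.0, 10.0),
        mid_point=(0.0, 0.0, 0.0),
        outlet_point=(0.0, -10.0, 10.0),
        canal_radius=3.0,
        grid_size=80,
        spacing=0.8,
    )
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def fine_straight_phantom():
    """Straight phantom, r=5 mm, length 30 mm, 0.4 mm spacing."""
    spec = PhantomSpec(
        inlet_point=(0.0, 0.0, 15.0),
        outlet_point=(0.0, 0.0, -15.0),
        canal_radius=5.0,
        grid_size=144,
        spacing=0.4,
    )
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
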