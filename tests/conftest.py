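import numpy as np
import pytest

import vesselac as va


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def y_phantom_clean():
    return va.render_phantom(va.default_y_phantom(seed=1, noise_fraction=0.0))


@pytest.fixture(scope="session")
def y_phantom_noisy():
    return va.render_phantom(va.default_y_phantom(seed=1, noise_fraction=0.28))


@pytest.fixture(scope="session")
def tube_phantom():
    """Straight horizontal tube of width 5 px, intensity 1, 5% noise."""
    spec = va.PhantomSpec(
        height=64,
        width=96,
        branches=(
            va.Branch(points=((32.0, 8.0), (32.0, 88.0)), half_width=2.5, intensity=1.0),
        ),
        noise_fraction=0.05,
        seed=7,
    )
    return va.render_phantom(spec)


@pytest.fixture(scope="session")
def tube_phantom_clean():
    spec = va.PhantomSpec(
        height=64,
        width=96,
        branches=(
            va.Branch(points=((32.0, 8.0), (32.0, 88.0)), half_width=2.5, intensity=1.0),
        ),
        noise_fraction=0.0,
        seed=0,
    )
    return va.render_phantom(spec)
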