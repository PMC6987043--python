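import pytest

import snapqsar as sq


@pytest.fixture(scope="session")
def methane():
    return sq.make_toy_molecule("methane")


@pytest.fixture(scope="session")
def benzene():
    return sq.make_toy_molecule("benzene")


@pytest.fixture(scope="session")
def small_dataset():
    """Separable synthetic benchmark small enough for fast tests."""
    spec = sq.SyntheticSpec(n_per_class=12, seed=7)
    return sq.make_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def fast_render():
    """Reduced-resolution render config for speed-sensitive tests."""
    return sq.RenderConfig(image_px=96)
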