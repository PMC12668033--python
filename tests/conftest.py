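import numpy as np
import pytest

from lewyseg.synthetic import (
    DETECTABLE_FAMILIES,
    make_threshold_fixture,
    render_tile,
    sample_scene,
)


@pytest.fixture(scope="session")
def threshold_fixture():
    return make_threshold_fixture()


@pytest.fixture(scope="session")
def small_scene():
    """One 256-px tile with 3 well-separated aggregates and 2 microglia."""
    spec = sample_scene(
        3, tile_size=256, seed=42, families=DETECTABLE_FAMILIES, n_dab=2
    )
    return render_tile(spec)


@pytest.fixture(scope="session")
def control_scene():
    """Control tile: hematoxylin background and microglia, no magenta."""
    spec = sample_scene(0, tile_size=256, seed=7, n_dab=2)
    return render_tile(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
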