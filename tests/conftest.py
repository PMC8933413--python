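import numpy as np
import pytest

from canopylai import (
    Appearance,
    SceneSpec,
    rasterize,
    render_rgb,
    simulate_scene,
)


@pytest.fixture(scope="session")
def small_poisson_scene():
    """A quick Poisson scene (3 m, 150 px/m, LAI 1) shared across tests."""
    spec = SceneSpec(target_lai=1.0, extent=3.0, resolution=150.0, D=0.09, seed=1)
    return simulate_scene(spec)


@pytest.fixture(scope="session")
def small_poisson_mask(small_poisson_scene):
    return rasterize(small_poisson_scene)


@pytest.fixture(scope="session")
def clean_render(small_poisson_scene):
    """Noise-free render plus its ground-truth mask."""
    return render_rgb(small_poisson_scene, Appearance(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
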