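import numpy as np
import pytest

from rmekit.scenes import CellSpec, SceneSpec, render_scene


@pytest.fixture
def single_cell_scene():
    """Noise-free single-cell scene factory: scene(f, **cell_kwargs)."""

    def make(membrane_fraction=0.0, seed=0, noise=0.0, **cell_kwargs):
        spec = SceneSpec(
            image_shape=(128, 128),
            cells=(
                CellSpec(
                    center=(64.0, 64.0),
                    membrane_fraction=membrane_fraction,
                    **cell_kwargs,
                ),
            ),
            noise_gaussian_sd=noise,
            seed=seed,
        )
        return render_scene(spec)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
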