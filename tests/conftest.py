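import numpy as np
import pytest

from dermaquant import GapMask, TextureParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_texture_params():
    """Fast, noise-free texture with clean two-level intensity separation."""
    return TextureParams(
        height_px=200, width_px=200, banner_rows=0, n_cells=10,
        gap_intensity_mean=30.0, cell_intensity_mean=200.0,
        noise_sd=0.0, detachment_fraction=0.0, rng_seed=7,
    )


def make_mask(arr) -> GapMask:
    """Wrap a boolean array as a GapMask for contour/count tests."""
    return GapMask(mask=np.asarray(arr, dtype=bool), threshold_value=0.0, source_max=0)
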