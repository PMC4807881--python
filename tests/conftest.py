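import numpy as np
import pytest

from hemoquant import synthetic as syn
from hemoquant.stack import Calibration

#: generator noise switched off — for tests that need the ideal forward model
NOISE_FREE = dict(shot_noise_scale=0.0, read_noise_sd=0.0, blur_sigma_um=0.0)


@pytest.fixture
def calib() -> Calibration:
    return Calibration(pixel_size_um=0.1, z_step_um=0.5)


@pytest.fixture
def noise_free_scene():
    """A clean 2-channel cell stack with one 2 µm vacuole and its truth."""
    spec = syn.SceneSpec(
        a_radius_um=5.0,
        b_height_um=3.0,
        vacuoles=[((0.0, 0.5, 0.5), 2.0)],
        seed=1,
        **NOISE_FREE,
    )
    return syn.make_cell_scene(spec)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
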