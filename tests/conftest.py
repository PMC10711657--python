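import numpy as np
import pytest
from hypothesis import settings

from tntkit import pattern_qc, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def d15_geometry():
    """Study geometry: 31-um circles with a 15-um edge gap (d = 46 um)."""
    return pattern_qc.PatternGeometry(
        diameter_um=31.0, separation_um=15.0, pixel_size_um=1.0
    )


@pytest.fixture(scope="session")
def d15_image(d15_geometry):
    image, truth = simulate.gen_pattern_image(
        d15_geometry, canvas_px=(512, 512), noise_sd=0.0, seed=11
    )
    return image, truth


@pytest.fixture(scope="session")
def noiseless_tube():
    """Blur-free, noise-free tube image: closed-form checks stay exact."""
    params = simulate.TubeSimParams(
        tube_length_um=15.0, ell_um=3.0, i0=50.0, noise="none", blur_um=0.0
    )
    image, truth = simulate.gen_tube_image(params, seed=7)
    return image, truth, params


def tube_axial_positions(n=5, lo_um=6.0, hi_um=13.0):
    """Arc-length sample positions on the tube (axis starts 3 um inside the cell)."""
    return np.linspace(lo_um, hi_um, n)
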