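import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from imsroi.cube import CoordinateIndex, DataCube
from imsroi.phantom import PhantomConfig, generate_phantom


def small_phantom_config(**overrides) -> PhantomConfig:
    """48×48 phantom with the same four-layer geometry, for fast tests."""
    kwargs = dict(
        grid_shape=(48, 48),
        arc_center=(70.0, 23.5),
        r_wm=37.0,
        r_gl=47.0,
        w_pcl=2.0,
        r_ml=62.0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """(cube, truth class map) on the 48×48 grid, default noise, seed 1."""
    return generate_phantom(small_phantom_config(), seed=1)


@pytest.fixture(scope="session")
def default_phantom():
    """(cube, truth class map) at the full default 96×96 study conditions."""
    return generate_phantom(PhantomConfig(), seed=1)


@pytest.fixture()
def tiny_cube():
    """3-pixel, 5-peak cube with hand-set values on a 2×2 grid."""
    coords = CoordinateIndex(
        pixel_xy=np.array([[0, 0], [1, 0], [0, 1]]), grid_shape=(2, 2)
    )
    intensities = np.array(
        [
            [0.0, 1.0, 4.0, 9.0, 16.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [1.5, 2.5, 3.5, 4.5, 5.5],
        ]
    )
    mz = np.array([100.0, 200.5, 300.25, 400.125, 500.0625])
    return DataCube(intensities=intensities, mz_axis=mz, coords=coords)
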