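import numpy as np
import pytest

from rdstereo.geometry import DisplayGeometry
from rdstereo.rds import RDSParams


@pytest.fixture(scope="session")
def reference_geometry() -> DisplayGeometry:
    """The 23-in 16:9 4K panel viewed at 5 m."""
    return DisplayGeometry(
        diagonal_mm=584.2,
        aspect_ratio=(16, 9),
        resolution_px=(3840, 2160),
        viewing_distance_mm=5000.0,
    )


@pytest.fixture(scope="session")
def small_geometry() -> DisplayGeometry:
    """Same panel and distance at a reduced pixel grid, for fast tests.

    The pitch is 4x coarser than the reference panel, so pixel shifts
    are about a quarter of the full-resolution ones.
    """
    return DisplayGeometry(
        diagonal_mm=584.2,
        aspect_ratio=(16, 9),
        resolution_px=(960, 540),
        viewing_distance_mm=5000.0,
    )


@pytest.fixture()
def small_params(small_geometry) -> RDSParams:
    return RDSParams(canvas_px=small_geometry.resolution_px, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
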