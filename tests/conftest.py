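import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from habsuit import GridRaster, LandscapeConfig


@pytest.fixture
def small_config():
    return LandscapeConfig(extent=(0.0, 0.0, 200.0, 200.0), cell_size_m=1.0,
                           formation_fraction=0.3, seed=11)


@pytest.fixture
def flat_raster():
    return GridRaster(np.zeros((20, 20)), 0.0, 0.0, 1.0, "flat")


def make_plane(slope_x=0.0, slope_y=0.0, n=20, cell=1.0):
    """DEM z = slope_x * x + slope_y * y on an n x n grid."""
    g = GridRaster(np.zeros((n, n)), 0.0, 0.0, cell, "plane")
    xs, ys = g.cell_centers()
    return g.like(slope_x * xs[None, :] + slope_y * ys[:, None])
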