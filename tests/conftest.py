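import numpy as np
import pytest
from hypothesis import settings

from spheroquant.dose import SurvivalParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def lq_params():
    """Plain LQ radiation parameters, no thermal response."""
    return SurvivalParams(alpha0=0.3, beta=0.03)


@pytest.fixture
def combined_params():
    """Parameters exercising every term of the combined model."""
    return SurvivalParams(
        alpha0=0.3, beta=0.03, a_thermal=0.025, b_thermal=0.0, c_sens=0.05
    )


def rasterize_disc(shape, centre, radius):
    """Boolean disc mask (row, col) — shared ground-truth helper."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


def rasterize_ellipse(shape, centre, semi_row, semi_col):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - centre[0]) / semi_row) ** 2 + (
        (xx - centre[1]) / semi_col
    ) ** 2 <= 1.0
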