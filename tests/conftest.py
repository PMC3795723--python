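"""Shared fixtures: direction sets, acquisition schemes, and component bases."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diffdecomp as dd
from diffdecomp.model import default_directions, single_fiber_basis

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

MD = 1.0e-3  # mm^2/s, mean diffusivity of the stock study


@pytest.fixture(scope="session")
def dirs():
    """The 321 antipodally-reduced axes of the frequency-8 tessellation."""
    return default_directions()


@pytest.fixture(scope="session")
def btable():
    """160-direction b=1500 s/mm^2 shell plus one b0 row."""
    return dd.shell_scheme(160, 1500.0)


@pytest.fixture(scope="session")
def basis(dirs, btable):
    """Component basis from the noise-free FA-0.7 single-fiber characteristic."""
    return single_fiber_basis(btable, dirs, fa=0.7, md=MD, f0=0.0)
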