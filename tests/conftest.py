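import numpy as np
import pytest

from spotfts import (
    LensletGrid,
    PSFModel,
    SystemConfig,
    lenslet_diffraction_limit,
)
from spotfts.optics import viewing_angles


@pytest.fixture(scope="session")
def paper_config():
    """The demonstrated system: 60x/1.4NA, 2.86x relay, 500 um MLA, 4x relay2."""
    return SystemConfig()


@pytest.fixture(scope="session")
def paper_grid(paper_config):
    return LensletGrid.build(paper_config)


@pytest.fixture(scope="session")
def paper_angles(paper_config, paper_grid):
    return viewing_angles(paper_grid, paper_config)


@pytest.fixture(scope="session")
def paper_psf(paper_config):
    return PSFModel(lenslet_diffraction_limit(paper_config))


@pytest.fixture(scope="session")
def wide_grid_config():
    """Reduced relay demagnification so all 36 lenslets have real viewing
    angles (6x6 angle grid up to ~43 degrees)."""
    return SystemConfig(relay_demag=1.5)


@pytest.fixture(scope="session")
def narrow_grid_config():
    """Gentler angle set (to ~30 degrees): large missing cone, useful for
    axial-anisotropy checks."""
    return SystemConfig(relay_demag=1.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
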