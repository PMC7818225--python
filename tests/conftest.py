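import numpy as np
import pytest

from erprep.montage import make_default_montage
from erprep.volume import FrameInterpolator, ScalpGrid, project_electrodes


@pytest.fixture(scope="session")
def montage():
    return make_default_montage()


@pytest.fixture(scope="session")
def grid():
    return ScalpGrid()


@pytest.fixture(scope="session")
def coords(montage, grid):
    return project_electrodes(montage, grid)


@pytest.fixture(scope="session")
def interp(coords, grid):
    return FrameInterpolator(coords, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
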