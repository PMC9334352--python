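import numpy as np
import pytest

from recoloc import LocalizationSet, tessellate


@pytest.fixture
def square_center_tess():
    """Five seeds: unit-square corners plus the centre. The centre's cell is
    the diamond with vertices (0.5,0),(1,0.5),(0.5,1),(0,0.5); corner cells
    are unbounded."""
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], dtype=float)
    return tessellate(LocalizationSet(pts))


@pytest.fixture
def cube_center_tess():
    """Unit-cube corners plus the centre in 3D. The centre's cell is the L1
    ball |u|+|v|+|w| <= 0.75 about the centre."""
    pts = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        + [[0.5, 0.5, 0.5]],
        dtype=float,
    )
    return tessellate(LocalizationSet(pts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
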