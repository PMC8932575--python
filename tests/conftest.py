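import numpy as np
import pytest

from epivertex.mesh import Cell, TissueState
from epivertex.mechanics import MechanicsParams
from epivertex.scenarios import make_fixture, make_hex_patch


@pytest.fixture
def unit_square():
    """A single unit-square cell."""
    return TissueState(
        vertices=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        cells={0: Cell(vertices=[0, 1, 2, 3])},
    )


@pytest.fixture
def hexagon():
    """A single regular hexagon with side 1."""
    ang = np.arange(6) * np.pi / 3.0
    return TissueState(
        vertices=np.stack([np.cos(ang), np.sin(ang)], axis=1),
        cells={0: Cell(vertices=[0, 1, 2, 3, 4, 5])},
    )


@pytest.fixture(scope="session")
def hex_patch():
    """5x5 patch of regular hexagons (session-wide, read-only)."""
    return make_hex_patch(5, 5)


@pytest.fixture(scope="session")
def circle_tissue():
    """Relaxed ~50-cell circular fixture (session-wide, read-only).

    Tests that mutate it must copy() first."""
    return make_fixture("circle", seed=11)


@pytest.fixture
def params():
    return MechanicsParams()
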