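import numpy as np
import pytest

from trypocycle import CellCycleMap


@pytest.fixture(scope="session")
def cmap() -> CellCycleMap:
    """Default procyclic cell-cycle map (0.596/0.852/0.942 u, 8.9 h)."""
    return CellCycleMap()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
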