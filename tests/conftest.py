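import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from latticedrift import LatticeConfig, PopulationGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def grid_from(copies) -> PopulationGrid:
    """Build a PopulationGrid from a nested list / array of copy counts."""
    arr = np.asarray(copies, dtype=np.int8)
    return PopulationGrid(LatticeConfig(*arr.shape), arr)
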