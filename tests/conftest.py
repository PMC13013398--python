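import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rngxe import Pedigree, SimulationConfig, simulate


@pytest.fixture
def trio_pedigree():
    """Sire, dam, offspring; parents unrelated."""
    return Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 1, 2)])


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return Pedigree.from_records(
        [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)]
    )


@pytest.fixture(scope="session")
def small_simulation():
    """~200 phenotyped animals in 10 CGs; shared across tests for speed."""
    cfg = SimulationConfig(n_founders=100, n_generations=2, n_cgs=10, seed=42)
    ped, records, truth = simulate(cfg)
    return cfg, ped, records, truth
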