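import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from cnvsmoke.simdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-subject cohort with a handful of panel components."""
    cfg = SimulationConfig(n_subjects=500, n_components=10, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
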