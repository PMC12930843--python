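import numpy as np
import pytest

import seqalignatac as sa


@pytest.fixture
def small_pair():
    """A small, easily separable simulated source/target pair."""
    cfg = sa.SimConfig(n_types=3, cells_per_type_source=25, cells_per_type_target=25,
                       n_peaks=300, seed=7)
    return sa.simulate_pair(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
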