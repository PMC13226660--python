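import numpy as np
import pytest

from secscreen import SimConfig


@pytest.fixture
def small_config():
    """A scaled-down study that keeps every planted structure."""
    return SimConfig(
        seed=1,
        n_genes=300,
        n_samples_per_tissue=60,
        n_tissues=8,
        n_cells_per_cluster=[120, 80, 9],
        module_size=20,
        n_broad=20,
        n_sc_background=60,
        n_responsive=40,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
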