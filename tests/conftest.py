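import numpy as np
import pytest

from oplskit import SimConfig, generate_cohort
from oplskit.core_io import group_vector


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (9+9, 95 metabolites)."""
    table, meta, standards, truth = generate_cohort(SimConfig(seed=1))
    return table, meta, standards, truth


@pytest.fixture(scope="session")
def default_xy(default_cohort):
    table, meta, _, _ = default_cohort
    return table.areas.copy(), group_vector(table, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
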