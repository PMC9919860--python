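import numpy as np
import pytest

import qsarfep as q


@pytest.fixture(scope="session")
def series():
    """Default synthetic congeneric series (seed 1)."""
    return q.generate_ligand_series(q.SyntheticSeriesSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(series):
    """Full QSAR pipeline on the seed-1 series."""
    mset, acts = series
    return q.qsar_pipeline(mset, acts, seed=1, n_boot=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
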