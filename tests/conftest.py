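import numpy as np
import pandas as pd
import pytest

from protbridge import ExpressionMatrix, SimConfig
from protbridge.harmonize import PLATFORM_APTAMER, PLATFORM_PEA


def make_matrix(values, platform=PLATFORM_APTAMER, scale="standardized",
                sample_ids=None, assay_ids=None):
    """Small ExpressionMatrix from a nested list / array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    assay_ids = assay_ids or [f"a{j}" for j in range(p)]
    df = pd.DataFrame(values, index=sample_ids, columns=assay_ids)
    return ExpressionMatrix(df, platform=platform, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sim_config():
    """Desk-scale simulator configuration used across unit tests."""
    return SimConfig(n_samples=300, n_proteins=20, block_sizes=(5, 5, 5, 5), seed=7)


@pytest.fixture
def platforms():
    return PLATFORM_APTAMER, PLATFORM_PEA
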