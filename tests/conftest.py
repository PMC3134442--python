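import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rncmap.containers import RatioMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def small_matrix(rng):
    """12 genes x 4 replicates, a few missing cells, no planted signal."""
    values = rng.normal(0, 1, (12, 4))
    values[2, 1] = np.nan
    values[7, 3] = np.nan
    data = pd.DataFrame(
        values,
        index=[f"g{i:02d}" for i in range(12)],
        columns=[f"r{j}" for j in range(4)],
    )
    return RatioMatrix(data, condition="test")
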