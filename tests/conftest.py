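import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """A 30-gene x 40-sample matrix with one strong 10-gene module."""
    n = 40
    factor = rng.standard_normal(n)
    rows = []
    for i in range(10):
        rows.append(0.8 * factor + 0.6 * rng.standard_normal(n))
    for i in range(20):
        rows.append(rng.standard_normal(n))
    return pd.DataFrame(
        rows,
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j:02d}" for j in range(n)],
    )
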