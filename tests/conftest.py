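import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, one missing value."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, np.nan, 7.0, 8.0], [2.0, 2.0, 2.0, 2.0]],
        index=pd.Index(["g1", "g2", "g3"], name="ID"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_group_matrix(rng):
    """200 random genes over 8 + 8 samples with labels."""
    X = rng.normal(0.0, 1.0, size=(200, 16))
    m = pd.DataFrame(
        X,
        index=[f"g{i}" for i in range(200)],
        columns=[f"s{i}" for i in range(16)],
    )
    labels = np.array(["A"] * 8 + ["B"] * 8)
    return m, labels
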