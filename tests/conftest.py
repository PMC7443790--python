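import numpy as np
import pandas as pd
import pytest

from lingbrain.matrix import FeatureMatrix


def block_from_array(X, prefix="f", ids=None, **kw) -> FeatureMatrix:
    """Wrap a 2-D array as a FeatureMatrix with generated names."""
    X = np.asarray(X, dtype=float)
    ids = ids or [f"sub{i:03d}" for i in range(X.shape[0])]
    cols = [f"{prefix}{j:03d}" for j in range(X.shape[1])]
    return FeatureMatrix(pd.DataFrame(X, index=ids, columns=cols), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_block():
    return block_from_array
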