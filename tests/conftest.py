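import numpy as np
import pytest

import cropcast as cc
from cropcast import preprocess as pp


@pytest.fixture(scope="session")
def small_ds():
    """A small clean synthetic draw (5 x 60 records)."""
    ds, _ = cc.generate(cc.SyntheticConfig(n_per_crop=60, seed=0))
    return ds


@pytest.fixture(scope="session")
def normalized_ds(small_ds):
    """The small draw min-max normalized on its own extremes."""
    params = pp.minmax_fit(small_ds)
    return pp.minmax_apply(small_ds, params)


@pytest.fixture(scope="session")
def default_ds():
    """The full default draw (5 x 1400 records), shared across tests."""
    ds, truth = cc.generate()
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
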