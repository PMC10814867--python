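import numpy as np
import pytest

from ziber.data import Dataset, ZIBerParams


def random_dataset(rng, n=30, p_extra=2, k_extra=1):
    """Small random dataset with both outcome classes present."""
    for _ in range(100):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p_extra))])
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, k_extra))])
        y = (rng.random(n) < 0.35).astype(float)
        if 0.0 < y.mean() < 1.0:
            return Dataset(y=y, X=X, Z=Z)
    raise RuntimeError("could not draw a non-degenerate dataset")


def random_params(rng, data, scale=1.0):
    return ZIBerParams(beta=scale * rng.standard_normal(data.p),
                       theta=scale * rng.standard_normal(data.k))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
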