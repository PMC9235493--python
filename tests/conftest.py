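import numpy as np
import pytest

from hiblock.io import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, prefix="F", sample_prefix="s", kinds=None):
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    return FeatureTable(
        [f"{prefix}{i}" for i in range(n_f)],
        [f"{sample_prefix}{j}" for j in range(n_s)],
        values,
        kinds or ["continuous"] * n_f,
    )


@pytest.fixture
def small_pair(rng):
    """Two aligned 6-feature tables with one planted perfect 2x2 block."""
    X = rng.standard_normal((6, 40))
    Y = rng.standard_normal((6, 40))
    z = rng.standard_normal(40)
    X[0] = z
    X[1] = z + 0.01 * rng.standard_normal(40)
    Y[0] = 2 * z + 1
    Y[1] = -z + 0.01 * rng.standard_normal(40)
    return make_table(X, "X"), make_table(Y, "Y")
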