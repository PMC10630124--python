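import numpy as np
import pytest

from gsfa.io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """3 cells x 2 genes with hand-checkable totals."""
    return CountMatrix(
        np.array([[5, 1], [2, 4], [7, 0]]),
        ["c1", "c2", "c3"],
        ["gA", "gB"],
    )


@pytest.fixture
def small_counts(rng):
    """Modest random count matrix with heterogeneous totals."""
    lam = rng.gamma(2.0, 2.0, size=(30, 12))
    counts = rng.poisson(lam * rng.uniform(0.5, 2.0, size=(30, 1)))
    counts[:, 0] += 1  # guarantee nonzero cell totals
    return CountMatrix(
        counts,
        [f"c{i}" for i in range(30)],
        [f"g{j}" for j in range(12)],
    )
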