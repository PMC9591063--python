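import numpy as np
import pytest

from orderica import make_dataset, whiten


@pytest.fixture(scope="session")
def two_source_white():
    """Whitened mixture of Laplace + uniform sources (N=2, M=20000)."""
    x, truth = make_dataset(["laplace", "uniform"], 20000, seed=11)
    xw, model = whiten(x)
    return xw, model, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
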