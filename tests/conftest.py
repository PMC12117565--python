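import numpy as np
import pytest

import escatter as es


@pytest.fixture(scope="session")
def toy20():
    return es.make_toy(20, seed=3)


@pytest.fixture(scope="session")
def graphene3x3():
    return es.make_graphene(3, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_qvecs(rng, n, qmax):
    """Random q-vectors uniform in direction, uniform in |q| up to qmax."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0.0, qmax, (n, 1))
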