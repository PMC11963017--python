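import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, q, batch=(), cond=10.0):
    """Random SPD matrices with bounded condition number."""
    shape = tuple(batch) + (q, q)
    A = rng.standard_normal(shape)
    Q, _ = np.linalg.qr(A)
    w = np.exp(rng.uniform(0, np.log(cond), size=tuple(batch) + (q,)))
    return (Q * w[..., None, :]) @ np.swapaxes(Q, -1, -2)


@pytest.fixture
def spd_factory(rng):
    def make(q, batch=(), cond=10.0):
        return random_spd(rng, q, batch, cond)

    return make
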