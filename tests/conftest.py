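import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def random_box(rng, lo=0.0, hi=100.0, min_side=0.5):
    x1, y1 = rng.uniform(lo, hi - min_side, 2)
    w, h = rng.uniform(min_side, (hi - lo) / 2, 2)
    return np.array([x1, y1, min(x1 + w, hi), min(y1 + h, hi)])
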