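import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


# --- independent brute-force oracles (written against the layer definitions,
# --- never against the vectorized implementation) -------------------------

def conv_oracle(x, kernels, biases, stride=1):
    """Direct six-nested-loop valid cross-correlation."""
    c_in, h, w = x.shape
    n_out, _, kh, kw = kernels.shape
    ho, wo = (h - kh) // stride + 1, (w - kw) // stride + 1
    y = np.zeros((n_out, ho, wo))
    for o in range(n_out):
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for c in range(c_in):
                    for a in range(kh):
                        for b in range(kw):
                            acc += x[c, i * stride + a, j * stride + b] * kernels[o, c, a, b]
                y[o, i, j] = acc + biases[o]
    return y


def pool_oracle(x):
    """Exhaustive per-window max for 2x2 stride-2 pooling."""
    c_in, h, w = x.shape
    y = np.zeros((c_in, h // 2, w // 2))
    for c in range(c_in):
        for i in range(h // 2):
            for j in range(w // 2):
                y[c, i, j] = max(x[c, 2 * i + a, 2 * j + b]
                                 for a in range(2) for b in range(2))
    return y


@pytest.fixture
def conv_loop_oracle():
    return conv_oracle


@pytest.fixture
def pool_loop_oracle():
    return pool_oracle
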