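"""Forward and backward primitives for the nodule-classification network.

Every layer the network uses lives here as a pair of pure functions
(``*_forward`` / ``*_backward``) over plain :class:`numpy.ndarray` feature-map
stacks, together with a central-difference numeric-gradient oracle used by the
test suite and acceptance checks.

Conventions
-----------
* A feature-map stack is indexed ``(channel, row, col)``; a leading batch axis
  ``(batch, channel, row, col)`` is accepted everywhere and results keep the
  rank of their input.
* Convolution is the cross-correlation orientation (no kernel flip), "valid"
  placement (no padding), the convention universal in CNN practice.
* Downsampling is 2x2 stride-2 max pooling; on ties the first maximum in
  row-major window order is selected and receives the full gradient.
* Accumulation is done in float64 regardless of input dtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_forward",
    "conv_backward",
    "relu",
    "relu_backward",
    "maxpool_forward",
    "maxpool_backward",
    "PoolIndexRecord",
    "fc_forward",
    "fc_backward",
    "softmax",
    "cross_entropy_loss",
    "softmax_ce_backward",
    "numeric_gradient",
    "relative_deviation",
    "numeric_gradient_check",
]

#: probabilities are clamped to [PROB_EPS, 1] before taking logs
PROB_EPS = 1e-12


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Promote a (C, H, W) stack to (1, C, H, W); report whether it was 3-D."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a 3-D or 4-D feature-map stack, got ndim={x.ndim}")


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv_forward(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray,
                 stride: int = 1) -> np.ndarray:
    """Valid cross-correlation of ``x`` with a kernel bank.

    Parameters
    ----------
    x : (C, H, W) or (N, C, H, W) array
    kernels : (O, C, kh, kw) array
    biases : (O,) array, one bias per output map
    stride : kernel step, >= 1

    Returns
    -------
    (O, Ho, Wo) or (N, O, Ho, Wo) array with
    ``Ho = (H - kh) / stride + 1`` and likewise for ``Wo``.
    """
    x4, squeeze = _as_batch(x)
    kernels = np.asarray(kernels, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)
    if kernels.ndim != 4:
        raise ValueError(f"kernel bank must be 4-D (out, in, kh, kw), got ndim={kernels.ndim}")
    n_out, n_in, kh, kw = kernels.shape
    _, c, h, w = x4.shape
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if c != n_in:
        raise ValueError(
            f"channel mismatch: input has {c} channels but kernels expect {n_in}")
    if h < kh or w < kw:
        raise ValueError(f"input {h}x{w} smaller than kernel {kh}x{kw}")
    if (h - kh) % stride or (w - kw) % stride:
        raise ValueError(
            f"non-integer output dimension: ({h}-{kh})/{stride} or ({w}-{kw})/{stride}")
    windows = sliding_window_view(x4, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    y = np.einsum("nchwij,ocij->nohw", windows, kernels, optimize=True)
    y += biases[None, :, None, None]
    return y[0] if squeeze else y


def conv_backward(grad_y: np.ndarray, x: np.ndarray, kernels: np.ndarray,
                  stride: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a conv layer w.r.t. input, kernels and biases.

    ``x`` and ``kernels`` are the cached forward operands; ``grad_y`` is the
    upstream gradient with the shape of the forward output.
    """
    if x is None or kernels is None:
        raise ValueError("conv_backward requires the cached forward input and kernels")
    x4, squeeze = _as_batch(x)
    g4, _ = _as_batch(grad_y)
    kernels = np.asarray(kernels, dtype=np.float64)
    n_out, n_in, kh, kw = kernels.shape
    n, _, ho, wo = g4.shape

    grad_b = g4.sum(axis=(0, 2, 3))
    windows = sliding_window_view(x4, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    grad_k = np.einsum("nohw,nchwij->ocij", g4, windows, optimize=True)

    grad_x = np.zeros_like(x4)
    for i in range(kh):
        for j in range(kw):
            grad_x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                np.einsum("nohw,oc->nchw", g4, kernels[:, :, i, j], optimize=True)
    return (grad_x[0] if squeeze else grad_x), grad_k, grad_b


# ---------------------------------------------------------------------------
# ReLU
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise ``max(0, x)``."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def relu_backward(grad_y: np.ndarray, x_pre: np.ndarray) -> np.ndarray:
    """Route the upstream gradient through the positive part of ``x_pre``."""
    if x_pre is None:
        raise ValueError("relu_backward requires the cached pre-activation")
    return np.asarray(grad_y, dtype=np.float64) * (np.asarray(x_pre) > 0)


# ---------------------------------------------------------------------------
# max pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolIndexRecord:
    """Argmax bookkeeping for routing gradients through 2x2/2 max pooling.

    ``flat`` holds, per pooled cell, the row-major index 0..3 of the selected
    maximum within its window; ``input_shape`` is the (batched) forward input
    shape and ``squeeze`` whether the forward input was unbatched.
    """

    flat: np.ndarray
    input_shape: tuple[int, ...]
    squeeze: bool

    @property
    def offsets(self) -> np.ndarray:
        """(…, 2) array of (row, col) offsets of each selected maximum."""
        return np.stack([self.flat // 2, self.flat % 2], axis=-1)


def maxpool_forward(x: np.ndarray, window: int = 2, stride: int = 2
                    ) -> tuple[np.ndarray, PoolIndexRecord]:
    """2x2 stride-2 max pooling, ``Y = max(X)`` per window."""
    if window != 2 or stride != 2:
        raise ValueError("only 2x2 windows with stride 2 are supported")
    x4, squeeze = _as_batch(x)
    n, c, h, w = x4.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool_forward requires even spatial dims, got {h}x{w}")
    cells = (x4.reshape(n, c, h // 2, 2, w // 2, 2)
             .transpose(0, 1, 2, 4, 3, 5)
             .reshape(n, c, h // 2, w // 2, 4))
    flat = cells.argmax(axis=-1)  # argmax -> first maximum on ties (row-major)
    y = np.take_along_axis(cells, flat[..., None], axis=-1)[..., 0]
    record = PoolIndexRecord(flat=flat, input_shape=x4.shape, squeeze=squeeze)
    return (y[0] if squeeze else y), record


def maxpool_backward(grad_y: np.ndarray, record: PoolIndexRecord) -> np.ndarray:
    """Scatter the upstream gradient to the recorded argmax positions."""
    if record is None:
        raise ValueError("maxpool_backward requires the forward PoolIndexRecord")
    g4, _ = _as_batch(grad_y)
    n, c, h, w = record.input_shape
    cells = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float64)
    np.put_along_axis(cells, record.flat[..., None], g4[..., None], axis=-1)
    grad_x = (cells.reshape(n, c, h // 2, w // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h, w))
    return grad_x[0] if record.squeeze else grad_x


# ---------------------------------------------------------------------------
# fully connected
# ---------------------------------------------------------------------------

def fc_forward(x: np.ndarray, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Affine map ``w @ x + b`` for a (D,) vector or (N, D) batch.

    ``weights`` has shape (out, in): its column count must equal the input
    length.
    """
    x = np.asarray(x, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)
    if x.shape[-1] != weights.shape[1]:
        raise ValueError(
            f"dimension mismatch: input length {x.shape[-1]} vs weight columns {weights.shape[1]}")
    return x @ weights.T + biases


def fc_backward(grad_y: np.ndarray, x: np.ndarray, weights: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the affine map w.r.t. input, weights and biases."""
    if x is None or weights is None:
        raise ValueError("fc_backward requires the cached forward input and weights")
    g = np.asarray(grad_y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    single = g.ndim == 1
    g2 = g[None] if single else g
    x2 = x[None] if single else x
    grad_w = g2.T @ x2
    grad_b = g2.sum(axis=0)
    grad_x = g2 @ weights
    return (grad_x[0] if single else grad_x), grad_w, grad_b


# ---------------------------------------------------------------------------
# softmax + cross-entropy
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the last axis (max logit subtracted before exp)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probs: np.ndarray, label) -> np.ndarray | float:
    """``-log p[label]`` with probabilities clamped to ``[1e-12, 1]``.

    Accepts a single probability vector with an integer label, or an (N, K)
    batch with an (N,) label array (returns per-sample losses).
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 1:
        return float(-np.log(np.clip(p[int(label)], PROB_EPS, 1.0)))
    picked = np.take_along_axis(p, np.asarray(label, dtype=np.intp)[:, None], axis=1)[:, 0]
    return -np.log(np.clip(picked, PROB_EPS, 1.0))


def softmax_ce_backward(probs: np.ndarray, label) -> np.ndarray:
    """Combined softmax + cross-entropy gradient w.r.t. logits: ``p - onehot``."""
    if probs is None:
        raise ValueError("softmax_ce_backward requires the cached probabilities")
    p = np.asarray(probs, dtype=np.float64)
    grad = p.copy()
    if p.ndim == 1:
        grad[int(label)] -= 1.0
        return grad
    rows = np.arange(p.shape[0])
    grad[rows, np.asarray(label, dtype=np.intp)] -= 1.0
    return grad


# ---------------------------------------------------------------------------
# numeric-gradient oracle
# ---------------------------------------------------------------------------

def numeric_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar-valued ``f`` w.r.t. array ``x``."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad


def relative_deviation(analytic: np.ndarray, numeric: np.ndarray,
                       eps: float = 1e-5) -> float:
    """Max over entries of ``|a - n| / max(|a|, |n|, eps)``."""
    a = np.asarray(analytic, dtype=np.float64)
    n = np.asarray(numeric, dtype=np.float64)
    denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), eps)
    return float(np.max(np.abs(a - n) / denom))


def numeric_gradient_check(f, arrays: dict[str, np.ndarray],
                           analytic: dict[str, np.ndarray],
                           eps: float = 1e-5) -> float:
    """Compare analytic gradients against central differences.

    ``f`` maps the dict of arrays (perturbed in place) to a scalar;
    ``analytic`` holds the gradients to verify, keyed like ``arrays``.
    Returns the maximum relative deviation over all arrays.
    """
    worst = 0.0
    for name, arr in arrays.items():
        num = numeric_gradient(lambda _a: f(arrays), arr, eps=eps)
        worst = max(worst, relative_deviation(analytic[name], num, eps=eps))
    return worst
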