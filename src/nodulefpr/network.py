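"""Network assembly for the nodule / nonnodule classifier.

The default architecture takes a single-channel 32x32 ROI patch (1024 input
units) through two conv(5x5, stride 1) + maxpool(2x2, stride 2) stages with 8
and 16 feature maps, then fully connected layers of 150, 100, 50 and 2 nodes,
finishing in a two-class softmax.  ReLU follows every conv and every hidden fc
layer; the final fc layer feeds the softmax directly.  Class indexing follows
the labels: index 0 = nonnodule, index 1 = nodule.

A 64x64 (or any other square single-channel) variant is expressed by building
a :class:`NetworkConfig` by hand; no default is claimed for it.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import tensor_core as tc

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "LayerParams",
    "ParameterSet",
    "conv",
    "maxpool",
    "fc",
    "softmax_layer",
    "default_config_32",
    "infer_shapes",
    "init_parameters",
    "forward",
    "forward_batch",
    "backward_batch",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "network_gradient_deviation",
]

CHECKPOINT_MAGIC = b"NFPRCKPT"
CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One layer of the stack.

    kind is one of ``conv``, ``maxpool``, ``fc``, ``softmax``.  For conv/fc
    layers ``activation`` selects whether ReLU follows the affine step
    (``relu``) or not (``linear``, used for the final logits layer).
    """

    kind: str
    feature_maps: int | None = None
    node_count: int | None = None
    kernel_size: int | None = None
    stride: int | None = None
    activation: str = "relu"

    def __post_init__(self):
        if self.kind not in {"conv", "maxpool", "fc", "softmax"}:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in {"relu", "linear"}:
            raise ValueError(f"unknown activation {self.activation!r}")


def conv(feature_maps: int, kernel_size: int = 5, stride: int = 1,
         activation: str = "relu") -> LayerSpec:
    return LayerSpec("conv", feature_maps=feature_maps, kernel_size=kernel_size,
                     stride=stride, activation=activation)


def maxpool(kernel_size: int = 2, stride: int = 2) -> LayerSpec:
    return LayerSpec("maxpool", kernel_size=kernel_size, stride=stride)


def fc(node_count: int, activation: str = "relu") -> LayerSpec:
    return LayerSpec("fc", node_count=node_count, activation=activation)


def softmax_layer() -> LayerSpec:
    return LayerSpec("softmax", activation="linear")


@dataclass(frozen=True)
class NetworkConfig:
    """Square single-channel input of ``input_size`` pixels per side, plus an
    ordered layer stack ending in a two-class softmax."""

    input_size: int
    layers: tuple[LayerSpec, ...]
    n_classes: int = 2

    def __post_init__(self):
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ValueError("the final layer must be softmax")
        fcs = [s for s in self.layers if s.kind == "fc"]
        if not fcs or fcs[-1].node_count != self.n_classes:
            raise ValueError(f"the last fc layer must have {self.n_classes} nodes")


def default_config_32(conv1_maps: int = 8, conv2_maps: int = 16) -> NetworkConfig:
    """The stock 32x32 network: conv8-pool-conv16-pool-fc150-fc100-fc50-fc2-softmax.

    The first-layer map count is exposed as a knob (some training protocols
    vary it); the default is 8.
    """
    return NetworkConfig(
        input_size=32,
        layers=(
            conv(conv1_maps, 5, 1),
            maxpool(),
            conv(conv2_maps, 5, 1),
            maxpool(),
            fc(150),
            fc(100),
            fc(50),
            fc(2, activation="linear"),
            softmax_layer(),
        ),
    )


def infer_shapes(config: NetworkConfig) -> list[int]:
    """Flattened activation count after each layer, input count first.

    For the stock 32x32 network this yields
    ``[1024, 6272, 1568, 1600, 400, 150, 100, 50, 2, 2]``.
    Raises if any conv/pool output dimension fails to be a positive integer,
    naming the offending layer.
    """
    c, h, w = 1, config.input_size, config.input_size
    counts = [c * h * w]
    flat: int | None = None
    for i, spec in enumerate(config.layers):
        name = f"layer {i} ({spec.kind})"
        if spec.kind == "conv":
            if flat is not None:
                raise ValueError(f"{name}: conv after flattening is not supported")
            if (h - spec.kernel_size) % spec.stride or (w - spec.kernel_size) % spec.stride \
                    or h < spec.kernel_size or w < spec.kernel_size:
                raise ValueError(f"{name}: non-integer or non-positive output dimension "
                                 f"from {h}x{w} with kernel {spec.kernel_size}, stride {spec.stride}")
            h = (h - spec.kernel_size) // spec.stride + 1
            w = (w - spec.kernel_size) // spec.stride + 1
            c = spec.feature_maps
            counts.append(c * h * w)
        elif spec.kind == "maxpool":
            if flat is not None:
                raise ValueError(f"{name}: pool after flattening is not supported")
            if h % 2 or w % 2:
                raise ValueError(f"{name}: odd spatial dimension {h}x{w} cannot be 2x2-pooled")
            h, w = h // 2, w // 2
            counts.append(c * h * w)
        elif spec.kind == "fc":
            flat = spec.node_count
            counts.append(flat)
        else:  # softmax
            if flat is None:
                raise ValueError(f"{name}: softmax requires a preceding fc layer")
            counts.append(flat)
    return counts


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class LayerParams:
    """Weights/biases of one parameterized layer plus momentum velocities."""

    weights: np.ndarray
    biases: np.ndarray
    v_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    v_biases: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.v_weights is None:
            self.v_weights = np.zeros_like(self.weights)
        if self.v_biases is None:
            self.v_biases = np.zeros_like(self.biases)


@dataclass
class ParameterSet:
    """Per-layer parameters aligned with a NetworkConfig; ``None`` entries for
    layers without parameters (maxpool, softmax)."""

    layers: list[LayerParams | None]

    def parameterized(self):
        return [(i, p) for i, p in enumerate(self.layers) if p is not None]


def init_parameters(config: NetworkConfig, seed: int,
                    scheme: str = "glorot_uniform") -> ParameterSet:
    """Random weight initialization; biases and velocities start at zero.

    ``glorot_uniform`` draws from U(-b, b) with b = sqrt(6 / (fan_in + fan_out));
    ``he_normal`` draws from N(0, sqrt(2 / fan_in)).  Fully reproducible from
    the seed.
    """
    rng = np.random.default_rng(seed)
    c, h, w = 1, config.input_size, config.input_size
    flat: int | None = None
    layers: list[LayerParams | None] = []
    for spec in config.layers:
        if spec.kind == "conv":
            k = spec.kernel_size
            shape = (spec.feature_maps, c, k, k)
            fan_in, fan_out = c * k * k, spec.feature_maps * k * k
            layers.append(LayerParams(_draw(rng, shape, fan_in, fan_out, scheme),
                                      np.zeros(spec.feature_maps)))
            h = (h - k) // spec.stride + 1
            w = (w - k) // spec.stride + 1
            c = spec.feature_maps
        elif spec.kind == "maxpool":
            h, w = h // 2, w // 2
            layers.append(None)
        elif spec.kind == "fc":
            n_in = flat if flat is not None else c * h * w
            shape = (spec.node_count, n_in)
            layers.append(LayerParams(_draw(rng, shape, n_in, spec.node_count, scheme),
                                      np.zeros(spec.node_count)))
            flat = spec.node_count
        else:
            layers.append(None)
    return ParameterSet(layers)


def _draw(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
          scheme: str) -> np.ndarray:
    if scheme == "glorot_uniform":
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-bound, bound, size=shape)
    if scheme == "he_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    raise ValueError(f"unknown initialization scheme {scheme!r}")


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _coerce_input(config: NetworkConfig, patch) -> tuple[np.ndarray, bool]:
    """Accept an ImagePatch, a (S,S) / (1,S,S) array, or an (N,1,S,S) batch."""
    pixels = getattr(patch, "pixels", patch)
    x = np.asarray(pixels, dtype=np.float64)
    s = config.input_size
    single = True
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    elif x.ndim == 4:
        single = False
    else:
        raise ValueError(f"cannot interpret input of ndim {x.ndim}")
    if x.shape[1:] != (1, s, s):
        raise ValueError(f"input shape {x.shape[1:]} does not match "
                         f"(1, {s}, {s}) expected by the network")
    return x, single


def forward_batch(config: NetworkConfig, params: ParameterSet, x: np.ndarray
                  ) -> tuple[np.ndarray, list]:
    """Run an (N,1,S,S) batch through the stack.

    Returns (probs (N,2), caches); the cache list holds, per layer, whatever
    the matching backward step needs.
    """
    caches: list = []
    a: np.ndarray = x
    for spec, lp in zip(config.layers, params.layers):
        if spec.kind == "conv":
            pre = tc.conv_forward(a, lp.weights, lp.biases, stride=spec.stride)
            if spec.activation == "relu":
                out = tc.relu(pre)
            else:
                out = pre
            caches.append(("conv", a, pre))
            a = out
        elif spec.kind == "maxpool":
            out, record = tc.maxpool_forward(a)
            caches.append(("maxpool", record))
            a = out
        elif spec.kind == "fc":
            if a.ndim > 2:
                a = a.reshape(a.shape[0], -1)
            pre = tc.fc_forward(a, lp.weights, lp.biases)
            out = tc.relu(pre) if spec.activation == "relu" else pre
            caches.append(("fc", a, pre))
            a = out
        else:  # softmax
            probs = tc.softmax(a)
            caches.append(("softmax", probs))
            a = probs
    return a, caches


def forward(config: NetworkConfig, params: ParameterSet, patch
            ) -> tuple[np.ndarray, list]:
    """Probabilities (index 0 = nonnodule, 1 = nodule) for one patch or a batch."""
    x, single = _coerce_input(config, patch)
    probs, caches = forward_batch(config, params, x)
    return (probs[0] if single else probs), caches


def backward_batch(config: NetworkConfig, params: ParameterSet, caches: list,
                   labels: np.ndarray) -> list:
    """Mean-loss gradients for every parameterized layer.

    Returns a list parallel to ``params.layers``: dicts with ``weights`` /
    ``biases`` gradients, or ``None`` for parameterless layers.  Gradients are
    averaged over the batch (mean cross-entropy).
    """
    if not caches:
        raise ValueError("backward_batch requires the forward caches")
    labels = np.asarray(labels, dtype=np.intp)
    n = labels.shape[0]
    grads: list = [None] * len(config.layers)

    kind, probs = caches[-1]
    assert kind == "softmax"
    grad = tc.softmax_ce_backward(probs, labels) / n

    for i in range(len(config.layers) - 2, -1, -1):
        spec, lp, cache = config.layers[i], params.layers[i], caches[i]
        if spec.kind == "fc":
            _, a_in, pre = cache
            if spec.activation == "relu":
                grad = tc.relu_backward(grad, pre)
            grad, gw, gb = tc.fc_backward(grad, a_in, lp.weights)
            grads[i] = {"weights": gw, "biases": gb}
        elif spec.kind == "maxpool":
            _, record = cache
            if grad.ndim == 2:  # flattened by the first fc layer above
                n_b, c, h, w = (record.input_shape[0], record.input_shape[1],
                                record.input_shape[2] // 2, record.input_shape[3] // 2)
                grad = grad.reshape(n_b, c, h, w)
            grad = tc.maxpool_backward(grad, record)
        elif spec.kind == "conv":
            _, a_in, pre = cache
            if spec.activation == "relu":
                grad = tc.relu_backward(grad, pre)
            grad, gk, gb = tc.conv_backward(grad, a_in, lp.weights, stride=spec.stride)
            grads[i] = {"weights": gk, "biases": gb}
    return grads


def predict(probabilities: np.ndarray) -> int | np.ndarray:
    """Class label from a probability pair (or (N,2) batch).

    Argmax over classes; an exact tie is resolved to nonnodule (label 0), the
    conservative choice for a false-positive-reduction tool.
    """
    p = np.asarray(probabilities)
    if p.ndim == 1:
        return int(p[1] > p[0])
    return (p[:, 1] > p[:, 0]).astype(np.intp)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _config_to_dict(config: NetworkConfig) -> dict:
    return {"input_size": config.input_size, "n_classes": config.n_classes,
            "layers": [asdict(s) for s in config.layers]}


def _config_from_dict(d: dict) -> NetworkConfig:
    return NetworkConfig(input_size=d["input_size"], n_classes=d["n_classes"],
                         layers=tuple(LayerSpec(**s) for s in d["layers"]))


def save_checkpoint(config: NetworkConfig, params: ParameterSet, path) -> None:
    """Write a self-describing binary checkpoint (see docs/checkpoint_format.md).

    Layout: magic, version, uint32 header length, JSON header (config + array
    manifest), then the raw little-endian float64 arrays in manifest order.
    Round-trips are bit-exact.
    """
    arrays: list[tuple[str, np.ndarray]] = []
    for i, lp in params.parameterized():
        for part in ("weights", "biases", "v_weights", "v_biases"):
            arrays.append((f"layer{i}.{part}", np.asarray(getattr(lp, part), dtype="<f8")))
    header = {
        "format_version": CHECKPOINT_VERSION,
        "config": _config_to_dict(config),
        "arrays": [{"name": name, "shape": list(a.shape)} for name, a in arrays],
    }
    blob = json.dumps(header, sort_keys=True).encode("utf-8")
    buf = io.BytesIO()
    buf.write(CHECKPOINT_MAGIC)
    buf.write(struct.pack("<I", CHECKPOINT_VERSION))
    buf.write(struct.pack("<I", len(blob)))
    buf.write(blob)
    for _, a in arrays:
        buf.write(np.ascontiguousarray(a, dtype="<f8").tobytes())
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> tuple[NetworkConfig, ParameterSet]:
    """Read a checkpoint written by :func:`save_checkpoint`.

    Corrupt, truncated or version-mismatched files raise ``ValueError``
    without returning partial state.
    """
    raw = Path(path).read_bytes()
    if len(raw) < len(CHECKPOINT_MAGIC) + 8 or raw[:len(CHECKPOINT_MAGIC)] != CHECKPOINT_MAGIC:
        raise ValueError("not a nodulefpr checkpoint (bad magic)")
    off = len(CHECKPOINT_MAGIC)
    version, hlen = struct.unpack_from("<II", raw, off)
    off += 8
    if version != CHECKPOINT_VERSION:
        raise ValueError(f"checkpoint format version {version} not supported "
                         f"(expected {CHECKPOINT_VERSION})")
    if len(raw) < off + hlen:
        raise ValueError("truncated checkpoint: incomplete header")
    header = json.loads(raw[off:off + hlen].decode("utf-8"))
    off += hlen
    config = _config_from_dict(header["config"])
    values: dict[str, np.ndarray] = {}
    for entry in header["arrays"]:
        shape = tuple(entry["shape"])
        nbytes = int(np.prod(shape, dtype=np.int64)) * 8 if shape else 8
        if len(raw) < off + nbytes:
            raise ValueError(f"truncated checkpoint: array {entry['name']} incomplete")
        values[entry["name"]] = np.frombuffer(raw[off:off + nbytes],
                                              dtype="<f8").reshape(shape).copy()
        off += nbytes
    if off != len(raw):
        raise ValueError("trailing bytes after the last checkpoint array")
    params = init_parameters(config, seed=0)
    for i, lp in params.parameterized():
        try:
            lp.weights = values[f"layer{i}.weights"]
            lp.biases = values[f"layer{i}.biases"]
            lp.v_weights = values[f"layer{i}.v_weights"]
            lp.v_biases = values[f"layer{i}.v_biases"]
        except KeyError as exc:
            raise ValueError(f"checkpoint missing arrays for layer {i}") from exc
        if lp.weights.shape != lp.v_weights.shape or lp.biases.shape != lp.v_biases.shape:
            raise ValueError(f"inconsistent array shapes for layer {i}")
    return config, params


# ---------------------------------------------------------------------------
# end-to-end gradient verification
# ---------------------------------------------------------------------------

def network_gradient_deviation(config: NetworkConfig, params: ParameterSet,
                               x: np.ndarray, labels: np.ndarray,
                               rng: np.random.Generator,
                               samples_per_array: int = 8,
                               eps: float = 1e-5) -> float:
    """Spot-check analytic end-to-end gradients against central differences.

    For each parameter tensor, ``samples_per_array`` random coordinates are
    perturbed and the numeric derivative of the mean cross-entropy is compared
    with the analytic gradient; returns the max relative deviation.

    Central differences are only meaningful where the loss is differentiable:
    a coordinate whose perturbation crosses a ReLU kink or flips a max-pool
    argmax is detected by comparing difference quotients at two step sizes
    (they agree to O(eps^2) on smooth stretches) and excluded.
    """
    labels = np.asarray(labels, dtype=np.intp)

    def loss() -> float:
        probs, _ = forward_batch(config, params, x)
        return float(np.mean(tc.cross_entropy_loss(probs, labels)))

    probs, caches = forward_batch(config, params, x)
    grads = backward_batch(config, params, caches, labels)

    worst = 0.0
    for i, lp in params.parameterized():
        for part in ("weights", "biases"):
            arr = getattr(lp, part)
            g = grads[i][part]
            n_coords = min(samples_per_array, arr.size)
            coords = rng.choice(arr.size, size=n_coords, replace=False)
            flat = arr.reshape(-1)
            for c in coords:
                orig = flat[c]
                quotients = []
                for h in (eps, eps / 2):
                    flat[c] = orig + h
                    fp = loss()
                    flat[c] = orig - h
                    fm = loss()
                    quotients.append((fp - fm) / (2 * h))
                flat[c] = orig
                d1, d2 = quotients
                if abs(d1 - d2) > 1e-3 * max(abs(d1), abs(d2), eps):
                    continue  # kink within the stencil: not differentiable here
                ana = g.reshape(-1)[c]
                worst = max(worst, tc.relative_deviation(np.array(ana), np.array(d2), eps=eps))
    return worst
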