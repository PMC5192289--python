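"""Minibatch SGD with momentum for the nodule classifier.

The optimizer is classical momentum: per parameter tensor,
``v <- mu * v - eta * g`` then ``w <- w + v``.  The training set is
re-shuffled from a seeded generator at the start of every epoch.  Two
learning-rate schedules are provided:

* ``constant`` — eta never changes (the cross-validation protocol);
* ``decay_on_precision`` — once the training-set classification accuracy
  first reaches the threshold (default 0.85), eta is multiplied by the decay
  factor (default 5/6) at the end of that and every later epoch, so after
  ``d`` post-threshold epochs eta equals ``eta0 * (5/6)**d``.  A one-shot
  variant (single decay when the threshold is first met) is also available.

Training terminates at ``max_epochs``, earlier when the training precision
reaches ``target_accuracy`` (if set), or when the epoch loss has improved by
less than ``convergence_tol`` for ``convergence_patience`` consecutive
epochs.  A non-finite loss aborts with the diagnostic state attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tensor_core as tc
from .network import (NetworkConfig, ParameterSet, backward_batch, forward_batch,
                      init_parameters, predict)
from .roi_extraction import PatchDataset

__all__ = [
    "TrainingConfig",
    "TrainingState",
    "EpochMetrics",
    "TrainingDivergedError",
    "momentum_update",
    "update_learning_rate",
    "run_epoch",
    "compute_training_precision",
    "train",
    "history_frame",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults follow the published protocol: learning rate 5e-4, momentum 0.9,
    decay factor 5/6 triggered at training precision 0.85, a 50-epoch horizon.
    Batch size is not stated there; 32 is the package default.
    """

    learning_rate: float = 5e-4
    momentum: float = 0.9
    schedule: str = "constant"  # "constant" | "decay_on_precision"
    decay_factor: float = 5.0 / 6.0
    precision_threshold: float = 0.85
    decay_mode: str = "per_epoch"  # "per_epoch" | "one_shot"
    batch_size: int = 32
    max_epochs: int = 50
    target_accuracy: float | None = None
    convergence_tol: float = 1e-6
    convergence_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must lie in (0, 1)")
        if self.schedule not in {"constant", "decay_on_precision"}:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.decay_mode not in {"per_epoch", "one_shot"}:
            raise ValueError(f"unknown decay_mode {self.decay_mode!r}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class EpochMetrics:
    epoch: int
    loss: float
    precision: float
    learning_rate: float


@dataclass
class TrainingState:
    """Mutable bookkeeping carried across epochs."""

    learning_rate: float
    rng: np.random.Generator
    epoch: int = 0
    threshold_reached: bool = False
    decays_applied: int = 0
    history: list[EpochMetrics] = field(default_factory=list)
    stop_reason: str | None = None


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite; carries the state so far."""

    def __init__(self, message: str, state: TrainingState):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# optimizer pieces
# ---------------------------------------------------------------------------

def momentum_update(params: ParameterSet, grads: list, learning_rate: float,
                    momentum: float) -> ParameterSet:
    """Classical-momentum step, in place: v <- mu*v - eta*g; w <- w + v."""
    for i, lp in params.parameterized():
        g = grads[i]
        if g is None:
            raise ValueError(f"missing gradients for parameterized layer {i}")
        if g["weights"].shape != lp.weights.shape or g["biases"].shape != lp.biases.shape:
            raise ValueError(f"gradient shape mismatch at layer {i}")
        lp.v_weights = momentum * lp.v_weights - learning_rate * g["weights"]
        lp.v_biases = momentum * lp.v_biases - learning_rate * g["biases"]
        lp.weights = lp.weights + lp.v_weights
        lp.biases = lp.biases + lp.v_biases
    return params


def update_learning_rate(state: TrainingState, training_precision: float,
                         config: TrainingConfig) -> float:
    """End-of-epoch schedule step; returns (and installs) the new rate.

    Under ``decay_on_precision`` the epoch in which the precision first
    reaches the threshold already decays; the rate never increases even if
    the precision later drops below the threshold.
    """
    if config.schedule == "constant":
        return state.learning_rate
    if not state.threshold_reached and training_precision >= config.precision_threshold:
        state.threshold_reached = True
    if state.threshold_reached:
        if config.decay_mode == "per_epoch" or state.decays_applied == 0:
            state.learning_rate *= config.decay_factor
            state.decays_applied += 1
    return state.learning_rate


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def run_epoch(dataset: PatchDataset, net_config: NetworkConfig,
              params: ParameterSet, state: TrainingState,
              config: TrainingConfig) -> tuple[ParameterSet, EpochMetrics]:
    """One pass: shuffle, then forward / loss / backward / update per batch.

    The reported precision is the fraction of training examples classified
    correctly during the pass (each example scored by the parameters in force
    when its batch was visited); the reported loss is the example-weighted
    mean cross-entropy.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot run an epoch on an empty dataset")
    order = state.rng.permutation(n)
    total_loss = 0.0
    n_correct = 0
    for start in range(0, n, config.batch_size):
        idx = order[start:start + config.batch_size]
        X = dataset.X[idx].astype(np.float64)
        y = dataset.y[idx]
        probs, caches = forward_batch(net_config, params, X)
        losses = tc.cross_entropy_loss(probs, y)
        total_loss += float(np.sum(losses))
        n_correct += int(np.sum(predict(probs) == y))
        grads = backward_batch(net_config, params, caches, y)
        momentum_update(params, grads, state.learning_rate, config.momentum)
    metrics = EpochMetrics(epoch=state.epoch, loss=total_loss / n,
                           precision=n_correct / n,
                           learning_rate=state.learning_rate)
    return params, metrics


def compute_training_precision(net_config: NetworkConfig, params: ParameterSet,
                               dataset: PatchDataset, batch_size: int = 512) -> float:
    """Fraction of the dataset the current parameters classify correctly."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot score an empty dataset")
    n_correct = 0
    for start in range(0, n, batch_size):
        X = dataset.X[start:start + batch_size].astype(np.float64)
        probs, _ = forward_batch(net_config, params, X)
        n_correct += int(np.sum(predict(probs) == dataset.y[start:start + batch_size]))
    return n_correct / n


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def train(dataset: PatchDataset, net_config: NetworkConfig,
          config: TrainingConfig, params: ParameterSet | None = None,
          on_epoch_end=None) -> tuple[ParameterSet, TrainingState]:
    """Train to termination; (seed, config, dataset) fully determine the result.

    Weight initialization and epoch shuffling draw from independent streams
    derived from ``config.seed``.  ``on_epoch_end(params, state)``, when
    given, runs after each epoch's schedule update (used by the holdout
    protocol to score the fixed test set every epoch).
    """
    init_ss, shuffle_ss = np.random.SeedSequence(config.seed).spawn(2)
    if params is None:
        params = init_parameters(net_config, seed=init_ss)
    state = TrainingState(learning_rate=config.learning_rate,
                          rng=np.random.default_rng(shuffle_ss))
    stall = 0
    best_loss = np.inf
    for epoch in range(config.max_epochs):
        state.epoch = epoch
        params, metrics = run_epoch(dataset, net_config, params, state, config)
        if not np.isfinite(metrics.loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}", state)
        update_learning_rate(state, metrics.precision, config)
        metrics.learning_rate = state.learning_rate  # rate entering next epoch
        state.history.append(metrics)
        if on_epoch_end is not None:
            on_epoch_end(params, state)
        if config.target_accuracy is not None and \
                metrics.precision >= config.target_accuracy:
            state.stop_reason = "target_accuracy"
            break
        if best_loss - metrics.loss < config.convergence_tol:
            stall += 1
            if stall >= config.convergence_patience:
                state.stop_reason = "converged"
                break
        else:
            stall = 0
        best_loss = min(best_loss, metrics.loss)
    else:
        state.stop_reason = "max_epochs"
    if state.stop_reason is None:
        state.stop_reason = "max_epochs"
    return params, state


def history_frame(state: TrainingState) -> pd.DataFrame:
    """Per-epoch (epoch, loss, precision, learning_rate) as a DataFrame."""
    return pd.DataFrame([{"epoch": m.epoch, "loss": m.loss,
                          "precision": m.precision,
                          "learning_rate": m.learning_rate}
                         for m in state.history])


def plot_history(state: TrainingState, path=None):
    """Loss/precision and learning-rate curves (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = history_frame(state)
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0.plot(df["epoch"], df["loss"], label="loss")
    ax0.plot(df["epoch"], df["precision"], label="precision")
    ax0.set_xlabel("epoch")
    ax0.legend()
    ax1.plot(df["epoch"], df["learning_rate"])
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("learning rate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
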