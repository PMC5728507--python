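"""From-scratch multilayer perceptron with a mini-batch momentum-SGD trainer.

The network is a plain feedforward stack: each hidden layer computes
``f(x @ W + b)`` with a tanh or logistic-sigmoid nonlinearity; the output
head is softmax (classification, trained with negative log-likelihood) or
linear (regression, trained with mean squared error).  Training is
steepest-descent on mini-batches with classical momentum, a per-update
learning-rate decay and inverted dropout on hidden activations:

    lr_k = learning_rate / (1 + decay * k)          (k = update counter)
    v   <- momentum * v - lr_k * grad
    w   <- w + v

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

HiddenActivation = Literal["tanh", "sigmoid"]
OutputActivation = Literal["softmax", "linear"]
Task = Literal["classification", "regression"]

_PROB_FLOOR = 1e-12  # clamp before log so -log(0) never occurs


class ShapeError(ValueError):
    """Raised when layer input/weight dimensions do not chain."""


@dataclass
class TrainSettings:
    """Hyperparameters of the mini-batch SGD trainer.

    learning_rate
        Base step size, decayed per update as ``lr / (1 + decay * k)``.
    momentum
        Classical momentum coefficient in [0, 1).
    decay
        Per-update learning-rate decay, >= 0.
    dropout_rate
        Inverted-dropout probability on hidden activations, in [0, 1).
    """

    learning_rate: float
    momentum: float = 0.0
    decay: float = 0.0
    dropout_rate: float = 0.0
    epochs: int = 10
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must lie in [0, 1), got {self.momentum}")
        if self.decay < 0:
            raise ValueError(f"decay must be non-negative, got {self.decay}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be non-negative, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be positive, got {self.batch_size}")


@dataclass
class LossHistory:
    """Mean training loss per epoch; ``diverged`` flags a non-finite loss."""

    per_epoch_loss: list[float] = field(default_factory=list)
    diverged: bool = False

    @property
    def final_loss(self) -> float:
        if not self.per_epoch_loss:
            raise ValueError("empty loss history has no final loss")
        return self.per_epoch_loss[-1]


@dataclass
class MLPModel:
    """Layered weights/biases plus the activation and task settings.

    ``layer_weights[k]`` has shape (fan_in, fan_out); adjacent layers must
    chain (fan_out of layer k equals fan_in of layer k+1).  The output width
    is the number of classes for classification and 1 for regression.
    """

    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    hidden_activation: HiddenActivation = "tanh"
    output_activation: OutputActivation = "softmax"
    task: Task = "classification"

    def __post_init__(self) -> None:
        if len(self.layer_weights) != len(self.layer_biases):
            raise ShapeError("weights and biases lists differ in length")
        for k, (w, b) in enumerate(zip(self.layer_weights, self.layer_biases)):
            if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
                raise ShapeError(f"layer {k}: weight {w.shape} and bias {b.shape} mismatch")
            if k > 0 and self.layer_weights[k - 1].shape[1] != w.shape[0]:
                raise ShapeError(
                    f"layer {k}: fan_in {w.shape[0]} does not chain with "
                    f"previous fan_out {self.layer_weights[k - 1].shape[1]}"
                )
        if self.task == "regression" and self.layer_weights[-1].shape[1] != 1:
            raise ShapeError("regression model must have output width 1")

    @property
    def layer_sizes(self) -> list[int]:
        sizes = [w.shape[0] for w in self.layer_weights]
        sizes.append(self.layer_weights[-1].shape[1])
        return sizes

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)

    def copy(self) -> "MLPModel":
        return MLPModel(
            [w.copy() for w in self.layer_weights],
            [b.copy() for b in self.layer_biases],
            self.hidden_activation,
            self.output_activation,
            self.task,
        )


def init_mlp(
    layer_sizes: Sequence[int],
    task: Task = "classification",
    hidden_activation: HiddenActivation | None = None,
    seed: int = 0,
) -> MLPModel:
    """Build an MLP with uniform(-s, s) weights, s = 1 / sqrt(fan_in).

    Small near-zero initialization keeps early gradients large for the
    saturating activations.  Hidden activation defaults to tanh for
    classification and sigmoid for regression; biases start at zero.
    """
    if len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    if hidden_activation is None:
        hidden_activation = "tanh" if task == "classification" else "sigmoid"
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        s = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-s, s, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(
        weights,
        biases,
        hidden_activation=hidden_activation,
        output_activation="softmax" if task == "classification" else "linear",
        task=task,
    )


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "tanh":
        return np.tanh(z)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    if activation == "linear":
        return z
    if activation == "softmax":
        shifted = z - z.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation {activation!r}")


def forward_layer(
    inputs: np.ndarray,
    weights: np.ndarray,
    biases: np.ndarray,
    activation: str,
    layer_index: int = 0,
) -> np.ndarray:
    """One layer: ``activation(inputs @ weights + biases)``."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[-1] != weights.shape[0]:
        raise ShapeError(
            f"layer {layer_index}: input width {inputs.shape[-1]} does not match "
            f"weight fan-in {weights.shape[0]}"
        )
    return _activate(inputs @ weights + biases, activation)


def mse(
    actual: np.ndarray,
    predicted: np.ndarray,
    variant: Literal["mean", "half_sum"] = "mean",
) -> float:
    """Squared-error cost: per-sample residual dot product, averaged
    (``mean``) or halved-and-summed (``half_sum``)."""
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if actual.shape != predicted.shape:
        raise ShapeError(f"shape mismatch: {actual.shape} vs {predicted.shape}")
    if actual.size == 0:
        raise ValueError("empty input")
    sq = ((actual - predicted) ** 2).sum(axis=-1)
    if variant == "mean":
        return float(sq.mean())
    if variant == "half_sum":
        return float(0.5 * sq.sum())
    raise ValueError(f"unknown variant {variant!r}")


def nll_loss(class_probabilities: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class, probabilities clamped
    at 1e-12 before the log."""
    p = np.atleast_2d(np.asarray(class_probabilities, dtype=float))
    labels = np.asarray(true_labels, dtype=int).ravel()
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= p.shape[1]:
        raise IndexError(
            f"label out of range [0, {p.shape[1]}) in {labels[(labels < 0) | (labels >= p.shape[1])]}"
        )
    picked = np.clip(p[np.arange(p.shape[0]), labels], _PROB_FLOOR, None)
    return float(-np.log(picked).mean())


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _forward_cached(
    model: MLPModel,
    x: np.ndarray,
    dropout_rate: float,
    rng: np.random.Generator | None,
) -> tuple[list[np.ndarray], list[np.ndarray | None]]:
    """Forward pass keeping per-layer activations and dropout masks.

    Inverted dropout: kept hidden units are rescaled by 1/(1-p) during
    training so prediction needs no rescaling.  The output layer is never
    dropped.
    """
    activations = [x]
    masks: list[np.ndarray | None] = []
    a = x
    last = model.n_layers - 1
    for k, (w, b) in enumerate(zip(model.layer_weights, model.layer_biases)):
        act = model.output_activation if k == last else model.hidden_activation
        a = forward_layer(a, w, b, act, layer_index=k)
        if k != last and dropout_rate > 0.0 and rng is not None:
            keep = rng.random(a.shape) >= dropout_rate
            a = a * keep / (1.0 - dropout_rate)
            masks.append(keep)
        else:
            masks.append(None)
        activations.append(a)
    return activations, masks


def _loss_and_grads(
    model: MLPModel,
    x: np.ndarray,
    targets: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Batch loss and analytic gradients for every weight and bias.

    Classification pairs softmax with mean NLL (delta = (p - y)/n);
    regression pairs a linear head with the mean squared error
    (delta = 2 (pred - y)/n).
    """
    n = x.shape[0]
    activations, masks = _forward_cached(model, x, dropout_rate, rng)
    out = activations[-1]
    if model.task == "classification":
        labels = np.asarray(targets, dtype=int).ravel()
        loss = nll_loss(out, labels)
        delta = (out - _one_hot(labels, out.shape[1])) / n
    else:
        y = np.asarray(targets, dtype=float).reshape(n, -1)
        loss = mse(y, out, "mean")
        delta = 2.0 * (out - y) / n

    grads_w = [np.empty(0)] * model.n_layers
    grads_b = [np.empty(0)] * model.n_layers
    for k in range(model.n_layers - 1, -1, -1):
        grads_w[k] = activations[k].T @ delta
        grads_b[k] = delta.sum(axis=0)
        if k == 0:
            break
        da = delta @ model.layer_weights[k].T
        if masks[k - 1] is not None:
            da = da * masks[k - 1] / (1.0 - dropout_rate)
        a_prev = activations[k]
        if model.hidden_activation == "tanh":
            delta = da * (1.0 - a_prev**2)
        else:  # sigmoid
            delta = da * a_prev * (1.0 - a_prev)
    return loss, grads_w, grads_b


def sgd_train(
    model: MLPModel,
    features: np.ndarray,
    targets: np.ndarray,
    settings: TrainSettings,
) -> tuple[MLPModel, LossHistory]:
    """Mini-batch momentum SGD; returns a new model and the loss history.

    Samples are reshuffled every epoch; the last partial mini-batch is used
    as-is so every epoch sees all samples.  A non-finite batch loss aborts
    training and flags the history as diverged.
    """
    x = np.asarray(features, dtype=float)
    model = model.copy()
    history = LossHistory()
    if settings.epochs == 0:
        return model, history

    rng = np.random.default_rng(settings.seed)
    vel_w = [np.zeros_like(w) for w in model.layer_weights]
    vel_b = [np.zeros_like(b) for b in model.layer_biases]
    n = x.shape[0]
    targets = np.asarray(targets)
    update_count = 0

    for _ in range(settings.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            with np.errstate(over="ignore", invalid="ignore"):  # divergence is detected below
                loss, gw, gb = _loss_and_grads(
                    model, x[idx], targets[idx], settings.dropout_rate, rng
                )
            if not np.isfinite(loss):
                history.per_epoch_loss.append(float("inf"))
                history.diverged = True
                return model, history
            epoch_loss += loss * len(idx)
            lr = settings.learning_rate / (1.0 + settings.decay * update_count)
            update_count += 1
            for k in range(model.n_layers):
                vel_w[k] = settings.momentum * vel_w[k] - lr * gw[k]
                vel_b[k] = settings.momentum * vel_b[k] - lr * gb[k]
                model.layer_weights[k] += vel_w[k]
                model.layer_biases[k] += vel_b[k]
        history.per_epoch_loss.append(epoch_loss / n)
    return model, history


def predict(model: MLPModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw outputs plus argmax labels (classification) or scalar values
    (regression); dropout is disabled."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.layer_weights[0].shape[0]:
        raise ShapeError(
            f"feature width {x.shape[1]} does not match input layer "
            f"{model.layer_weights[0].shape[0]}"
        )
    activations, _ = _forward_cached(model, x, 0.0, None)
    out = activations[-1]
    if model.task == "classification":
        return out, out.argmax(axis=1)
    return out, out.ravel()


def save_model(
    model: MLPModel, path: str | Path, settings: TrainSettings | None = None
) -> None:
    """Serialize model (and optionally its TrainSettings) to JSON.

    JSON round-trips Python floats exactly (repr-based), so load_model
    reproduces the arrays bit for bit.
    """
    payload = {
        "layer_sizes": model.layer_sizes,
        "layer_weights": [w.tolist() for w in model.layer_weights],
        "layer_biases": [b.tolist() for b in model.layer_biases],
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "task": model.task,
        "train_settings": None if settings is None else vars(settings),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[MLPModel, TrainSettings | None]:
    payload = json.loads(Path(path).read_text())
    model = MLPModel(
        [np.array(w, dtype=float) for w in payload["layer_weights"]],
        [np.array(b, dtype=float) for b in payload["layer_biases"]],
        payload["hidden_activation"],
        payload["output_activation"],
        payload["task"],
    )
    ts = payload["train_settings"]
    return model, (TrainSettings(**ts) if ts is not None else None)
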