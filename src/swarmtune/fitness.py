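"""Particle scoring: λ-split the training data, train briefly, score held out.

A candidate configuration is scored by training a fresh network for a small
number of epochs with that candidate's hyperparameters on the inner training
subset Tr (a fraction λ of the data, default 0.8) and measuring it on the
held-out validation subset Te: classification accuracy, or negated MSE for
regression, so that larger is always better.  The split is made once per
search run so pbest scores stay comparable across generations.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .data import Dataset
from .encoding import NetworkConfig, SearchSpace, decode_particle
from .nn import LossHistory, MLPModel, TrainSettings, init_mlp, mse, predict, sgd_train

logger = logging.getLogger(__name__)


@dataclass
class EvalProtocol:
    """How candidates are trained and scored.

    eval_epochs is the short budget used while the swarm searches;
    final_epochs is the long budget for the final models.  `score_on`
    selects held-out validation scoring (default) or the last training loss.
    """

    task: Literal["classification", "regression"] = "classification"
    lambda_fraction: float = 0.8
    eval_epochs: int = 5
    final_epochs: int = 20
    batch_size: int = 100
    split_seed: int = 0
    score_on: Literal["validation", "training_loss"] = "validation"
    hidden_activation: Literal["tanh", "sigmoid"] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_fraction < 1.0:
            raise ValueError("lambda_fraction must lie strictly between 0 and 1")
        if self.eval_epochs < 1 or self.final_epochs < 1:
            raise ValueError("epoch counts must be positive")
        if self.eval_epochs > self.final_epochs:
            raise ValueError("eval_epochs must not exceed final_epochs")


def split_train_val(
    dataset: Dataset, lam: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Partition into Tr (floor(lam*n) records) and Te, stratified by class
    for classification."""
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must lie strictly between 0 and 1, got {lam}")
    n = dataset.n_samples
    n_train = int(np.floor(lam * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"lambda={lam} yields an empty split for n={n}")
    stratify = dataset.targets if dataset.task == "classification" else None
    train_idx, val_idx = train_test_split(
        np.arange(n), train_size=n_train, random_state=seed, stratify=stratify
    )
    tr, te = dataset.subset(train_idx), dataset.subset(val_idx)
    if dataset.task == "classification" and len(np.unique(tr.targets)) < dataset.n_classes:
        raise ValueError("a class is absent from the training split")
    return tr, te


def build_settings(
    config: NetworkConfig, epochs: int, batch_size: int, seed: int
) -> TrainSettings:
    """TrainSettings for a decoded configuration (composition with the
    trainer is total: any in-bounds config is a valid setting)."""
    return TrainSettings(
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        decay=config.decay,
        dropout_rate=config.dropout_rate,
        epochs=epochs,
        batch_size=min(batch_size, 10**9),
        seed=seed,
    )


def train_config(
    config: NetworkConfig,
    train: Dataset,
    protocol: EvalProtocol,
    epochs: int,
    seed: int,
) -> tuple[MLPModel, LossHistory]:
    """Train a fresh network specified by `config` on `train`."""
    if protocol.task == "classification":
        out_width = train.n_classes
    else:
        out_width = 1
    layers = [train.n_features, *config.hidden_layer_sizes, out_width]
    model = init_mlp(
        layers, task=protocol.task, hidden_activation=protocol.hidden_activation, seed=seed
    )
    settings = build_settings(config, epochs, protocol.batch_size, seed)
    return sgd_train(model, train.features, train.targets, settings)


def score_model(model: MLPModel, data: Dataset) -> float:
    """Validation score, maximization convention: accuracy or -MSE."""
    raw, out = predict(model, data.features)
    if model.task == "classification":
        return float(np.mean(out == data.targets))
    return -mse(np.asarray(data.targets, dtype=float)[:, None], raw, "mean")


def evaluate_config(
    config: NetworkConfig,
    train: Dataset,
    val: Dataset,
    protocol: EvalProtocol,
    seed: int,
) -> float:
    """Score one candidate: short training on Tr, scored on Te (or on its
    final training loss when score_on='training_loss').  Divergent training
    scores -inf."""
    model, history = train_config(config, train, protocol, protocol.eval_epochs, seed)
    if history.diverged:
        logger.warning("training diverged for config %s", config)
        return float("-inf")
    if protocol.score_on == "training_loss":
        score = -history.final_loss
    else:
        score = score_model(model, val)
    logger.debug("config %s -> score %.6g", config, score)
    return score


def derive_seed(master_seed: int, position: np.ndarray) -> int:
    """Deterministic 31-bit per-particle seed from the master seed and the
    particle's position bytes — duplicate positions share a seed."""
    digest = hashlib.blake2b(
        np.ascontiguousarray(position, dtype=float).tobytes()
        + int(master_seed).to_bytes(8, "little", signed=True),
        digest_size=4,
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


def batch_evaluate(
    positions: Sequence[np.ndarray],
    space: SearchSpace,
    train: Dataset,
    val: Dataset,
    protocol: EvalProtocol,
    seed: int,
) -> list[float]:
    """Decode and score a whole swarm; order-stable, per-particle seeds
    derived from the master seed."""
    return [
        evaluate_config(
            decode_particle(p, space), train, val, protocol, derive_seed(seed, p)
        )
        for p in positions
    ]


def make_fitness(
    space: SearchSpace,
    train: Dataset,
    val: Dataset,
    protocol: EvalProtocol,
    seed: int,
) -> Callable[[np.ndarray], float]:
    """Fitness closure over a fixed Tr/Te split, for run_pso."""

    def fitness(position: np.ndarray) -> float:
        return evaluate_config(
            decode_particle(position, space),
            train,
            val,
            protocol,
            derive_seed(seed, position),
        )

    return fitness
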