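"""Particle <-> network-configuration mapping.

A particle is an m-dimensional real vector with m = 4 + hidden_layer_count,
in the fixed component order (learning_rate, dropout_rate, momentum, decay,
neurons of hidden layer 1, neurons of hidden layer 2, ...).  The particle
stays continuous during the search; neuron components are rounded half-up to
integers only at decode time, so the PSO dynamics see a smooth box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Bounds = tuple[float, float]


@dataclass
class SearchSpace:
    """Per-hyperparameter bounds defining the particle box.

    The same neuron range applies to every hidden layer; the number of
    hidden layers is fixed per experiment (depth is not searched).  Defaults
    are the classification-regime ranges: learning rate [0.01, 0.9], dropout
    and momentum [0.1, 0.9], decay [1e-5, 1e-4], two hidden layers of
    [90, 150] neurons.
    """

    learning_rate_bounds: Bounds = (0.01, 0.9)
    dropout_bounds: Bounds = (0.1, 0.9)
    momentum_bounds: Bounds = (0.1, 0.9)
    decay_bounds: Bounds = (1e-5, 1e-4)
    hidden_layer_count: int = 2
    neuron_bounds: Bounds = (90, 150)

    _FIELD_BOUNDS = (
        ("learning_rate", "learning_rate_bounds"),
        ("dropout_rate", "dropout_bounds"),
        ("momentum", "momentum_bounds"),
        ("decay", "decay_bounds"),
    )

    def __post_init__(self) -> None:
        for _, attr in self._FIELD_BOUNDS:
            lo, hi = getattr(self, attr)
            if lo > hi:
                raise ValueError(f"{attr}: lower {lo} > upper {hi}")
        if self.hidden_layer_count < 1:
            raise ValueError("hidden_layer_count must be positive")
        nlo, nhi = self.neuron_bounds
        if nlo < 1 or nlo > nhi:
            raise ValueError(f"neuron_bounds invalid: {self.neuron_bounds}")

    @property
    def dimension(self) -> int:
        return 4 + self.hidden_layer_count

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) arrays in particle component order."""
        scalars = [getattr(self, attr) for _, attr in self._FIELD_BOUNDS]
        lower = [lo for lo, _ in scalars] + [self.neuron_bounds[0]] * self.hidden_layer_count
        upper = [hi for _, hi in scalars] + [self.neuron_bounds[1]] * self.hidden_layer_count
        return np.array(lower, dtype=float), np.array(upper, dtype=float)

    def neuron_int_bounds(self) -> tuple[int, int]:
        lo, hi = self.neuron_bounds
        return int(np.ceil(lo)), int(np.floor(hi))


@dataclass
class NetworkConfig:
    """Decoded phenotype of one particle: trainer hyperparameters plus the
    hidden-layer widths."""

    learning_rate: float
    dropout_rate: float
    momentum: float
    decay: float
    hidden_layer_sizes: list[int] = field(default_factory=list)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def decode_particle(position: np.ndarray, space: SearchSpace) -> NetworkConfig:
    """Map a particle vector to a NetworkConfig (neurons rounded half-up and
    clipped to their bounds)."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dimension,):
        raise ValueError(
            f"position has dimension {position.shape}, expected ({space.dimension},)"
        )
    nlo, nhi = space.neuron_int_bounds()
    neurons = np.clip(_round_half_up(position[4:]), nlo, nhi).astype(int)
    return NetworkConfig(
        learning_rate=float(position[0]),
        dropout_rate=float(position[1]),
        momentum=float(position[2]),
        decay=float(position[3]),
        hidden_layer_sizes=neurons.tolist(),
    )


def encode_config(config: NetworkConfig, space: SearchSpace) -> np.ndarray:
    """Inverse of decode_particle for in-bounds configs; integer hidden sizes
    are placed unchanged in the tail components."""
    if len(config.hidden_layer_sizes) != space.hidden_layer_count:
        raise ValueError(
            f"config has {len(config.hidden_layer_sizes)} hidden layers, "
            f"space expects {space.hidden_layer_count}"
        )
    for name, attr in SearchSpace._FIELD_BOUNDS:
        lo, hi = getattr(space, attr)
        value = getattr(config, name)
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")
    nlo, nhi = space.neuron_int_bounds()
    for size in config.hidden_layer_sizes:
        if not nlo <= size <= nhi:
            raise ValueError(f"hidden layer size {size} outside bounds [{nlo}, {nhi}]")
    return np.array(
        [config.learning_rate, config.dropout_rate, config.momentum, config.decay]
        + [float(s) for s in config.hidden_layer_sizes]
    )


def random_config(space: SearchSpace, rng: np.random.Generator) -> NetworkConfig:
    """Uniform draw: continuous fields over their bounds, neuron counts
    uniform over the integers in range."""
    nlo, nhi = space.neuron_int_bounds()
    return NetworkConfig(
        learning_rate=float(rng.uniform(*space.learning_rate_bounds)),
        dropout_rate=float(rng.uniform(*space.dropout_bounds)),
        momentum=float(rng.uniform(*space.momentum_bounds)),
        decay=float(rng.uniform(*space.decay_bounds)),
        hidden_layer_sizes=rng.integers(nlo, nhi + 1, size=space.hidden_layer_count).tolist(),
    )
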