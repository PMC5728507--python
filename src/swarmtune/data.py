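"""Synthetic fixtures, scaling and PCA preprocessing, and file I/O.

Two generator regimes mirror the studies this package targets:

* pixel-like classification data — dense Gaussian class clusters min-max
  scaled to [0, 1], standing in for handwritten-digit matrices;
* QSAR descriptor regression data — thousands of samples by thousands of
  correlated molecular descriptors with low-rank latent structure (hence
  PCA-reducible), scaled into the open interval (0, 1), with a bioactivity
  target that is a nonlinear function of a few latent factors.

File I/O covers CSV feature tables (one named label/target column) and the
IDX binary format (MNIST dialect) for optional real-image runs.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

FeatureScale = Literal["unit_interval", "open_unit_interval"]
_OPEN_MARGIN = 1e-3  # keeps open-interval data strictly inside (0, 1)


@dataclass
class Dataset:
    """Feature matrix with labels (classification) or real targets
    (regression)."""

    features: np.ndarray
    targets: np.ndarray
    task: Literal["classification", "regression"]
    feature_scale: FeatureScale = "unit_interval"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets)
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError(
                f"{self.features.shape[0]} feature rows vs {self.targets.shape[0]} targets"
            )
        if self.features.size == 0:
            raise ValueError("empty feature matrix")
        lo, hi = self.features.min(), self.features.max()
        if self.feature_scale == "unit_interval" and (lo < 0.0 or hi > 1.0):
            raise ValueError(f"features outside [0, 1]: range [{lo}, {hi}]")
        if self.feature_scale == "open_unit_interval" and (lo <= 0.0 or hi >= 1.0):
            raise ValueError(f"features outside (0, 1): range [{lo}, {hi}]")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        if self.task != "classification":
            raise ValueError("n_classes is only defined for classification data")
        return int(self.targets.max()) + 1

    def subset(self, indices: np.ndarray) -> "Dataset":
        return Dataset(
            self.features[indices], self.targets[indices], self.task, self.feature_scale
        )


def make_classification_data(
    n: int, d: int, n_classes: int = 3, separation: float = 3.0, seed: int = 0
) -> Dataset:
    """Near-balanced Gaussian class clusters, min-max scaled to [0, 1].

    Class means sit at distance ~`separation` (in within-class standard
    deviations) along random unit directions, so separation >= 3 gives an
    essentially linearly separable problem.
    """
    if n < n_classes * 10:
        raise ValueError(f"need n >= 10 * n_classes, got n={n}, n_classes={n_classes}")
    if d < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_classes, d))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = separation * directions
    labels = rng.permutation(np.arange(n) % n_classes)
    features = means[labels] + rng.normal(size=(n, d))
    features = scale_unit(features, "min_max")
    return Dataset(features, labels, "classification", "unit_interval")


def make_qsar_data(
    n_molecules: int,
    n_descriptors: int,
    latent_rank: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Dataset:
    """Descriptor matrix with low-rank latent structure and a nonlinear
    activity target, features scaled into (0, 1).

    Descriptors are latent factors times sparse loadings plus Gaussian
    noise, so a PCA of the matrix concentrates variance in ~latent_rank
    components.  The activity is a quadratic-plus-interaction function of
    the first three latent factors (offset away from zero so relative-error
    metrics are well defined) — learnable by a two-hidden-layer network but
    not by a linear model.
    """
    if latent_rank >= min(n_molecules, n_descriptors):
        raise ValueError("latent_rank must be < min(n_molecules, n_descriptors)")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_molecules, latent_rank))
    loadings = rng.normal(size=(latent_rank, n_descriptors))
    mask = rng.random(size=loadings.shape) < 0.3  # sparse descriptor coupling
    # every descriptor couples to at least one factor, else the per-column
    # rescaling below would inflate pure-noise columns to unit range
    dead = ~mask.any(axis=0)
    mask[rng.integers(0, latent_rank, size=int(dead.sum())), np.flatnonzero(dead)] = True
    loadings *= mask
    features = z @ loadings + noise_sd * rng.normal(size=(n_molecules, n_descriptors))
    features = scale_unit(features, "min_max")
    features = features * (1.0 - 2.0 * _OPEN_MARGIN) + _OPEN_MARGIN
    k = min(3, latent_rank)
    zz = np.pad(z[:, :k], ((0, 0), (0, 3 - k)))
    activity = 5.0 + zz[:, 0] ** 2 + zz[:, 1] * zz[:, 2] + zz[:, 0]
    activity = activity + noise_sd * rng.normal(size=n_molecules)
    return Dataset(features, activity, "regression", "open_unit_interval")


def scale_unit(
    features: np.ndarray, mode: Literal["divide_255", "min_max"]
) -> np.ndarray:
    """Scale features to the unit interval, by x/255 for 8-bit pixel data or
    per-column min-max (constant columns map to 0)."""
    features = np.asarray(features, dtype=float)
    if mode == "divide_255":
        if features.min() < 0 or features.max() > 255:
            raise ValueError("divide_255 requires values in [0, 255]")
        return features / 255.0
    if mode == "min_max":
        lo = features.min(axis=0, keepdims=True)
        rng_ = features.max(axis=0, keepdims=True) - lo
        safe = np.where(rng_ == 0, 1.0, rng_)
        out = (features - lo) / safe
        return np.where(rng_ == 0, 0.0, out)
    raise ValueError(f"unknown mode {mode!r}")


def pca_reduce(features: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Project centered features onto the top-k principal axes; returns the
    scores and per-component explained-variance fractions."""
    features = np.asarray(features, dtype=float)
    if not 1 <= k <= min(features.shape):
        raise ValueError(f"k={k} outside [1, {min(features.shape)}]")
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(features)
    return reduced, pca.explained_variance_ratio_


def components_for_variance(features: np.ndarray, fraction: float = 0.95) -> int:
    """Smallest component count whose cumulative explained variance reaches
    `fraction` (the default preprocessing dimensionality for descriptor
    matrices)."""
    _, ratios = pca_reduce(features, min(np.asarray(features).shape))
    return int(np.searchsorted(np.cumsum(ratios), fraction) + 1)


# ---------------------------------------------------------------------------
# CSV I/O

def save_dataset_csv(dataset: Dataset, path: str | Path, target_column: str = "target") -> None:
    frame = pd.DataFrame(
        dataset.features, columns=[f"f{i}" for i in range(dataset.n_features)]
    )
    frame[target_column] = dataset.targets
    frame.to_csv(path, index=False)


def load_dataset_csv(
    path: str | Path,
    task: Literal["classification", "regression"],
    target_column: str = "target",
    feature_scale: FeatureScale = "unit_interval",
) -> Dataset:
    frame = pd.read_csv(path)
    if target_column not in frame.columns:
        raise ValueError(f"target column {target_column!r} not in {list(frame.columns)}")
    targets = frame.pop(target_column).to_numpy()
    if task == "classification":
        targets = targets.astype(int)
    return Dataset(frame.to_numpy(dtype=float), targets, task, feature_scale)


# ---------------------------------------------------------------------------
# IDX (MNIST dialect) I/O: 2 zero bytes, dtype code, ndim, big-endian dims,
# row-major payload.

_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def read_idx(source: str | Path | BinaryIO) -> np.ndarray:
    """Read an IDX array, trusting the file header for dimensions."""
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = Path(source).read_bytes()
    if len(data) < 4 or data[0] != 0 or data[1] != 0:
        raise ValueError("not an IDX file: bad magic number")
    dtype_code, ndim = data[2], data[3]
    if dtype_code not in _IDX_DTYPES:
        raise ValueError(f"unknown IDX dtype code 0x{dtype_code:02x}")
    dims = struct.unpack(f">{ndim}I", data[4 : 4 + 4 * ndim])
    dtype = _IDX_DTYPES[dtype_code]
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = data[4 + 4 * ndim :]
    if len(payload) != expected:
        raise ValueError(f"IDX payload has {len(payload)} bytes, expected {expected}")
    return np.frombuffer(payload, dtype=dtype).reshape(dims).astype(dtype.newbyteorder("="))


def write_idx(array: np.ndarray, target: str | Path | BinaryIO) -> None:
    """Write an array in IDX format (dtype mapped to the nearest IDX code)."""
    array = np.asarray(array)
    code = {"u1": 0x08, "i1": 0x09, "i2": 0x0B, "i4": 0x0C, "f4": 0x0D, "f8": 0x0E}.get(
        array.dtype.str[1:]
    )
    if code is None:
        raise ValueError(f"dtype {array.dtype} not representable in IDX")
    header = bytes([0, 0, code, array.ndim]) + struct.pack(
        f">{array.ndim}I", *array.shape
    )
    payload = array.astype(array.dtype.newbyteorder(">")).tobytes()
    if hasattr(target, "write"):
        target.write(header + payload)
    else:
        Path(target).write_bytes(header + payload)
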