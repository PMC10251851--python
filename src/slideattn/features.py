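"""Per-patch feature extraction and autoencoder dimensionality reduction.

Feature extraction is pluggable: any callable mapping an RGB patch to a
fixed-length vector (declared via its ``dim`` attribute) can serve as the
encoder. The default offline encoder is a seeded random projection of the
downsampled patch; a pretrained CNN (e.g. a global-average-pooled
ResNet-50 trunk producing 2048-d vectors) can be plugged in through the
same interface when available.

Dimensionality reduction uses a single-hidden-layer autoencoder
(in -> hidden ReLU -> out linear, MSE loss, Adam), mirroring a 2048 -> 512
reduction at full scale; all dimensions are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ._optim import Adam


class RandomProjectionEncoder:
    """Seeded Gaussian random projection of a downsampled patch.

    Deterministic given (seed, dim, thumb): the patch is resized to
    ``thumb`` x ``thumb``, flattened with its 3 channels scaled to [0, 1],
    and multiplied by a fixed N(0, 1/sqrt(in_dim)) matrix.
    """

    def __init__(self, dim: int = 2048, thumb: int = 56, seed: int = 0) -> None:
        self.dim = dim
        self.thumb = thumb
        in_dim = thumb * thumb * 3
        rng = np.random.default_rng(seed)
        self.matrix = rng.standard_normal((dim, in_dim)) / np.sqrt(in_dim)

    def flatten(self, patch: np.ndarray) -> np.ndarray:
        small = resize(patch, (self.thumb, self.thumb), order=1,
                       preserve_range=True, anti_aliasing=True)
        return (small / 255.0).ravel()

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.matrix @ self.flatten(patch)


def extract_features(patches, encoder) -> np.ndarray:
    """Encode a list of RGB patches into an (N, dim) matrix, in order."""
    dim = getattr(encoder, "dim", None)
    rows = []
    for patch in patches:
        vec = np.asarray(encoder(patch), dtype=np.float64).ravel()
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                f"encoder returned {vec.size} dims, declared {dim}")
        rows.append(vec)
    if not rows:
        return np.empty((0, dim if dim is not None else 0))
    return np.vstack(rows)


@dataclass
class Standardizer:
    """Per-dimension z-scoring fitted on training folds only."""

    mean: np.ndarray = None
    std: np.ndarray = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean = x.mean(axis=0)
        self.std = np.maximum(x.std(axis=0), 1e-8)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


@dataclass
class ReducerModel:
    """Single-hidden-layer autoencoder for feature reduction.

    encode: relu(x W1^T + b1) -> hidden; decode: linear back to input
    space. ``training_log`` holds the per-epoch mean-squared
    reconstruction error.
    """

    w1: np.ndarray  # (hidden, in)
    b1: np.ndarray
    w2: np.ndarray  # (in, hidden)
    b2: np.ndarray
    training_log: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.w1.shape[0]

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim}-d features, got {x.shape[1]}")
        return np.maximum(x @ self.w1.T + self.b1, 0.0)

    def decode(self, h: np.ndarray) -> np.ndarray:
        return h @ self.w2.T + self.b2

    def reconstruction_mse(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=np.float64)
        return float(np.mean((self.decode(self.encode(x)) - x) ** 2))


def _init_reducer(input_dim: int, hidden_dim: int, rng) -> ReducerModel:
    s1 = np.sqrt(2.0 / input_dim)
    s2 = np.sqrt(2.0 / hidden_dim)
    return ReducerModel(
        w1=rng.standard_normal((hidden_dim, input_dim)) * s1,
        b1=np.zeros(hidden_dim),
        w2=rng.standard_normal((input_dim, hidden_dim)) * s2,
        b2=np.zeros(input_dim),
    )


def subsample_per_slide(features: np.ndarray, slide_ids, n_per_slide: int,
                        rng) -> np.ndarray:
    """At most ``n_per_slide`` randomly chosen rows from each slide."""
    slide_ids = np.asarray(slide_ids)
    keep = []
    for sid in pd_unique(slide_ids):
        idx = np.flatnonzero(slide_ids == sid)
        if idx.size > n_per_slide:
            idx = rng.choice(idx, size=n_per_slide, replace=False)
        keep.append(idx)
    return features[np.sort(np.concatenate(keep))]


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


def train_reducer(features: np.ndarray, hidden_dim: int = 512,
                  epochs: int = 100, batch_size: int = 256, lr: float = 1e-3,
                  sample_per_slide: int = 200, slide_ids=None,
                  seed: int = 0) -> ReducerModel:
    """Train the reduction autoencoder by Adam on mini-batches.

    When ``slide_ids`` is given, at most ``sample_per_slide`` patches per
    slide enter training (the usual way to keep the reducer's training set
    balanced across slides). ``epochs=0`` returns the initialized model
    with an empty log. Fewer training rows than ``hidden_dim`` triggers an
    under-determined warning but training proceeds.
    """
    x = np.asarray(features, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if slide_ids is not None:
        x = subsample_per_slide(x, slide_ids, sample_per_slide, rng)
    model = _init_reducer(x.shape[1], hidden_dim, rng)
    if x.shape[0] < hidden_dim:
        warnings.warn(
            f"{x.shape[0]} training rows < hidden size {hidden_dim}: "
            "the reducer is under-determined", stacklevel=2)
    if epochs == 0:
        return model

    params = [model.w1, model.b1, model.w2, model.b2]
    opt = Adam(params, lr=lr)
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = x[order[start:start + batch_size]]
            z = xb @ model.w1.T + model.b1
            h = np.maximum(z, 0.0)
            y = h @ model.w2.T + model.b2
            err = y - xb
            d_y = 2.0 * err / err.size
            g_w2 = d_y.T @ h
            g_b2 = d_y.sum(axis=0)
            d_h = d_y @ model.w2
            d_z = d_h * (z > 0)
            g_w1 = d_z.T @ xb
            g_b1 = d_z.sum(axis=0)
            opt.step([g_w1, g_b1, g_w2, g_b2])
        model.training_log.append(model.reconstruction_mse(x))
    return model


def reduce(model: ReducerModel, features: np.ndarray) -> np.ndarray:
    """Apply the trained encoder half; shape (N, hidden_dim)."""
    return model.encode(np.asarray(features, dtype=np.float64))
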