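"""Structure-preserving H&E stain normalization via sparse non-negative
stain separation.

In optical-density (OD) space stains mix linearly (Beer–Lambert):
``OD = C @ S`` with ``S`` the 2x3 stain matrix (rows are the unit-norm OD
color vectors of hematoxylin and eosin) and ``C`` the non-negative
per-pixel concentrations. The stain matrix of an image is estimated by
sparse non-negative dictionary learning (l1-penalized codes, non-negative
dictionary); normalization keeps the source's concentration field — hence
the tissue structure — and recombines it with a reference stain matrix
after per-stain scaling of the concentration ranges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DEFAULT_I0 = 255.0
DEFAULT_EPS = 1.0  # grey levels added before the log; guards log(0)

# Classical H&E OD color vectors (unit norm), used for the shipped
# synthetic reference fixture and as fallbacks for degenerate fits.
def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


CANONICAL_HEMATOXYLIN = _unit([0.650, 0.704, 0.286])
CANONICAL_EOSIN = _unit([0.072, 0.990, 0.105])


@dataclass
class ODImage:
    """Per-pixel optical densities with the incident intensity they refer to."""

    od: np.ndarray  # (..., 3), >= 0
    background_intensity: float = DEFAULT_I0


def rgb_to_od(image: np.ndarray, I0: float = DEFAULT_I0,
              eps: float = DEFAULT_EPS) -> ODImage:
    """Beer–Lambert transform: OD = -log10((pixel + eps) / I0), clipped at 0."""
    arr = np.asarray(image, dtype=np.float64)
    od = -np.log10((arr + eps) / I0)
    return ODImage(od=np.maximum(od, 0.0), background_intensity=I0)


def od_to_rgb(od: ODImage | np.ndarray, I0: float = DEFAULT_I0,
              eps: float = DEFAULT_EPS) -> np.ndarray:
    """Inverse transform back to 8-bit RGB (exact up to quantization)."""
    if isinstance(od, ODImage):
        I0 = od.background_intensity
        od = od.od
    rgb = I0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - eps
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


@dataclass
class StainModel:
    """Estimated stain appearance of one image.

    ``stain_matrix`` rows are the H and E OD vectors (non-negative, unit
    L2 norm, hematoxylin first); ``max_concentrations`` holds the
    99th-percentile concentration per stain, used to align concentration
    ranges between images.
    """

    stain_matrix: np.ndarray  # (2, 3)
    max_concentrations: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain_matrix must be non-negative")
        norms = np.linalg.norm(self.stain_matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix rows must be unit L2 norm")
        if (self.max_concentrations <= 0).any():
            raise ValueError("max_concentrations must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stain_matrix": self.stain_matrix.tolist(),
                       "max_concentrations": self.max_concentrations.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "StainModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["stain_matrix"]), np.asarray(d["max_concentrations"]))


def _tissue_mask(image: np.ndarray, gray_cutoff: float = 220.0,
                 sat_cutoff: float = 0.05) -> np.ndarray:
    """Non-background pixels by the same rule the patch filter uses."""
    from skimage.color import rgb2gray, rgb2hsv

    gray = rgb2gray(image) * 255.0
    sat = rgb2hsv(image)[..., 1]
    return ~((gray >= gray_cutoff) | (sat <= sat_cutoff))


def nnls_concentrations(od: np.ndarray, stain_matrix: np.ndarray,
                        l1: float = 0.0) -> np.ndarray:
    """Exact per-pixel non-negative least squares for the two-stain case.

    Minimizes ``0.5 ||od - C S||^2 + l1 * sum(C)`` over C >= 0 row-wise.
    With only two stains the active sets can be enumerated (both free /
    one clamped / both clamped), so the solution is exact and fully
    vectorized. On the non-negative orthant the l1 term only shifts the
    linear coefficient, so the same enumeration applies.
    """
    od = np.asarray(od, dtype=np.float64)
    flat = od.reshape(-1, 3)
    S = np.asarray(stain_matrix, dtype=np.float64)
    G = S @ S.T  # (2, 2)
    b = flat @ S.T - l1  # (N, 2)

    cands = np.zeros((4, flat.shape[0], 2))
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det > 1e-12:
        cands[0, :, 0] = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
        cands[0, :, 1] = (G[0, 0] * b[:, 1] - G[0, 1] * b[:, 0]) / det
    else:  # (near-)collinear stains: fall back to single-stain fits only
        cands[0] = -1.0
    cands[1, :, 0] = np.maximum(b[:, 0] / G[0, 0], 0.0)
    cands[2, :, 1] = np.maximum(b[:, 1] / G[1, 1], 0.0)
    # candidate 3 stays (0, 0)

    # objective f(c) = 0.5 c G c - c . b (constant ||od||^2 dropped)
    obj = 0.5 * np.einsum("kni,ij,knj->kn", cands, G, cands) - np.einsum(
        "kni,ni->kn", cands, b)
    obj[0][(cands[0] < 0).any(axis=1)] = np.inf
    best = np.argmin(obj, axis=0)
    conc = cands[best, np.arange(flat.shape[0])]
    return conc.reshape(od.shape[:-1] + (2,))


def _nnls_from_gram(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise exact solution of min 0.5 c G c - c . b over c >= 0 (2 vars)."""
    cands = np.zeros((4, b.shape[0], 2))
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det > 1e-12:
        cands[0, :, 0] = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
        cands[0, :, 1] = (G[0, 0] * b[:, 1] - G[0, 1] * b[:, 0]) / det
    else:
        cands[0] = -1.0
    if G[0, 0] > 1e-12:
        cands[1, :, 0] = np.maximum(b[:, 0] / G[0, 0], 0.0)
    if G[1, 1] > 1e-12:
        cands[2, :, 1] = np.maximum(b[:, 1] / G[1, 1], 0.0)
    obj = 0.5 * np.einsum("kni,ij,knj->kn", cands, G, cands) - np.einsum(
        "kni,ni->kn", cands, b)
    obj[0][(cands[0] < 0).any(axis=1)] = np.inf
    best = np.argmin(obj, axis=0)
    return cands[best, np.arange(b.shape[0])]


def sparse_nmf_stains(od: np.ndarray, sparsity_lambda: float = 0.1,
                      n_iter: int = 60, init: np.ndarray | None = None,
                      tol: float = 1e-8):
    """Two-stain sparse NMF by exact alternating minimization.

    Minimizes ``0.5 ||OD - C S||_F^2 + lambda ||C||_1`` over C >= 0 and
    S >= 0 (2x3, rows rescaled to unit norm each iteration). Both
    subproblems are two-variable non-negative quadratic programs solved
    exactly by active-set enumeration, so each alternation is a monotone
    block-coordinate step. Initialized at the classical H&E vectors unless
    ``init`` is given.

    Returns ``(S, C)`` with C the final sparse codes.
    """
    od = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    S = np.array(init if init is not None else
                 np.vstack([CANONICAL_HEMATOXYLIN, CANONICAL_EOSIN]), dtype=float)
    S = S / np.linalg.norm(S, axis=1, keepdims=True)
    C = None
    for _ in range(n_iter):
        C = nnls_concentrations(od, S, l1=sparsity_lambda)
        G = C.T @ C
        B = (C.T @ od).T  # (3, 2): one 2-var problem per color channel
        S_new = _nnls_from_gram(G, B).T  # (2, 3)
        norms = np.linalg.norm(S_new, axis=1)
        for i in range(2):  # collapsed stain (all-zero codes): keep old row
            if norms[i] < 1e-10:
                S_new[i] = S[i]
        S_new = S_new / np.linalg.norm(S_new, axis=1, keepdims=True)
        delta = float(np.abs(S_new - S).max())
        S = S_new
        if delta < tol:
            break
    return S, nnls_concentrations(od, S, l1=sparsity_lambda)


def _order_hematoxylin_first(S: np.ndarray) -> np.ndarray:
    """Row with the larger OD_red / OD_blue ratio is hematoxylin.

    Hematoxylin transmits blue light (low blue OD, high red OD); eosin the
    converse. A fixed convention keeps models composable.
    """
    ratios = (S[:, 0] + 1e-12) / (S[:, 2] + 1e-12)
    if ratios[0] >= ratios[1]:
        return S
    return S[::-1].copy()


def estimate_stain_model(image: np.ndarray, sparsity_lambda: float = 0.1,
                         max_pixels: int = 10_000, min_tissue_pixels: int = 200,
                         seed: int = 0) -> StainModel:
    """Fit a 2-stain sparse NMF model to the tissue pixels of an image.

    Dictionary learning solves ``OD ~ C S`` with non-negative ``S`` (rows
    then rescaled to unit norm) and sparse non-negative codes ``C``
    (l1 weight ``sparsity_lambda``), on a random sample of at most
    ``max_pixels`` non-background pixels.
    """
    image = np.asarray(image)
    tissue = _tissue_mask(image)
    n_tissue = int(tissue.sum())
    if n_tissue < min_tissue_pixels:
        raise ValueError(
            f"only {n_tissue} tissue pixels found (< {min_tissue_pixels}); "
            "provide a larger or less empty sample"
        )
    rng = np.random.default_rng(seed)
    pix = image.reshape(-1, 3)[tissue.ravel()]
    if pix.shape[0] > max_pixels:
        pix = pix[rng.choice(pix.shape[0], size=max_pixels, replace=False)]
    od = rgb_to_od(pix).od

    S, _ = sparse_nmf_stains(od, sparsity_lambda=sparsity_lambda)
    S = _order_hematoxylin_first(S)
    # concentration percentiles from the exact (unpenalized) transform,
    # matching what normalize_to_reference applies at mapping time
    conc = nnls_concentrations(od, S)
    max_c = np.maximum(np.percentile(conc, 99, axis=0), 1e-8)
    return StainModel(stain_matrix=S, max_concentrations=max_c)


def normalize_to_reference(source: np.ndarray, reference_model: StainModel,
                           source_model: StainModel) -> np.ndarray:
    """Map a source image to the reference stain appearance.

    Source concentrations are scaled per stain by reference_max/source_max
    and recombined with the reference stain matrix; the concentration field
    (tissue structure) is preserved up to that positive scaling.
    """
    source = np.asarray(source)
    od = rgb_to_od(source).od
    conc = nnls_concentrations(od, source_model.stain_matrix)
    src_max = source_model.max_concentrations
    scale = np.where(src_max > 1e-8,
                     reference_model.max_concentrations / np.maximum(src_max, 1e-8),
                     1.0)
    if (src_max <= 1e-8).any():
        warnings.warn("zero source max concentration; scale clamped to 1",
                      stacklevel=2)
    od_out = (conc * scale) @ reference_model.stain_matrix
    return od_to_rgb(ODImage(od=od_out))


def render_from_model(conc: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Render an RGB image from a concentration field and stain matrix."""
    od = np.asarray(conc) @ np.asarray(stain_matrix)
    return od_to_rgb(ODImage(od=od))


@lru_cache(maxsize=1)
def default_reference_model() -> StainModel:
    """Reference stain model fitted on a synthetic H&E-like fixture.

    The fixture is rendered from the classical H&E OD vectors with smooth
    random concentration fields, so the reference is reproducible without
    shipping any image data.
    """
    rng = np.random.default_rng(20230531)
    size = 96
    base = rng.gamma(shape=2.0, scale=0.35, size=(size, size, 2))
    img = render_from_model(base, np.vstack([CANONICAL_HEMATOXYLIN,
                                             CANONICAL_EOSIN]))
    return estimate_stain_model(img, seed=0)
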