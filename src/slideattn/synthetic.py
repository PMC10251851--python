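"""Synthetic slides, feature bags, and clinical cohorts for offline testing.

Real study cohorts (gigapixel H&E whole-slide images plus clinical tables)
cannot ship with the package, so this module generates stand-ins with the
statistical structure the downstream pipeline relies on:

* feature-space MIL bags obeying the standard multiple-instance assumption
  exactly — a bag is positive iff it contains at least one "witness"
  instance drawn from the positive-instance distribution;
* image-space toy slides with a per-pixel region mask over four texture
  classes (background, tumor, plain stroma, inflamed stroma), where the
  inflamed-stroma texture is the discriminative feature planted only in
  positive slides;
* per-patient clinical covariates (age, gender, pT stage, lymphovascular
  invasion, histologic grade) with labels drawn from a logistic model with
  known coefficients, so parameter-recovery tests have ground truth.

Nothing here aims at histological realism; textures are chosen so region
masks are trivially checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bags import FeatureBag

# region-mask codes
BACKGROUND = 0
TUMOR = 1
PLAIN_STROMA = 2
INFLAMED_STROMA = 3

REGION_NAMES = {
    BACKGROUND: "background",
    TUMOR: "tumor",
    PLAIN_STROMA: "plain_stroma",
    INFLAMED_STROMA: "inflamed_stroma",
}

COVARIATE_NAMES = ("age", "gender", "pT_stage", "LVI", "grade")


@dataclass
class BagSimConfig:
    """Configuration of the feature-space bag simulator.

    ``witness_rate`` is the expected fraction of positive instances in a
    positive bag; every positive bag receives ``max(1, round(witness_rate *
    bag_size))`` witnesses so the MIL assumption holds even at tiny rates.
    Negative bags contain no witnesses. Instances are isotropic Gaussians
    with mean ``mu_pos`` (witnesses) or ``mu_neg`` (all others) and shared
    standard deviation ``sigma``.
    """

    n_bags: int = 200
    bag_size: int = 50
    dim: int = 10
    witness_rate: float = 0.1
    class_balance: float = 0.5
    mu_neg: float | np.ndarray = 0.0
    mu_pos: float | np.ndarray = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags <= 0 or self.bag_size <= 0 or self.dim <= 0:
            raise ValueError("n_bags, bag_size and dim must be positive")
        if not (0.0 < self.witness_rate <= 1.0):
            raise ValueError("witness_rate must lie in (0, 1]")
        if not (0.0 <= self.class_balance <= 1.0):
            raise ValueError("class_balance must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def witnesses_per_positive_bag(self) -> int:
        return max(1, int(round(self.witness_rate * self.bag_size)))


def generate_bags(config: BagSimConfig) -> list[FeatureBag]:
    """Draw a reproducible list of feature bags from ``config``.

    Exactly ``round(n_bags * class_balance)`` bags are positive (assignment
    order shuffled); each positive bag carries the deterministic witness
    count of the config, negative bags carry none. Ground-truth witness
    flags are stored per instance.
    """
    rng = np.random.default_rng(config.seed)
    mu_neg = np.broadcast_to(np.asarray(config.mu_neg, dtype=float), (config.dim,))
    mu_pos = np.broadcast_to(np.asarray(config.mu_pos, dtype=float), (config.dim,))

    n_pos = int(round(config.n_bags * config.class_balance))
    labels = np.zeros(config.n_bags, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    bags = []
    for i, label in enumerate(labels):
        x = mu_neg + config.sigma * rng.standard_normal((config.bag_size, config.dim))
        witness = np.zeros(config.bag_size, dtype=bool)
        if label == 1:
            k = config.witnesses_per_positive_bag
            idx = rng.choice(config.bag_size, size=k, replace=False)
            witness[idx] = True
            x[idx] = mu_pos + config.sigma * rng.standard_normal((k, config.dim))
        bags.append(
            FeatureBag(
                slide_id=f"bag_{i:04d}",
                patient_id=f"pt_{i:04d}",
                label=int(label),
                features=x,
                witness=witness,
            )
        )
    return bags


@dataclass
class SyntheticSlide:
    """A rendered toy slide with its ground-truth region mask."""

    image: np.ndarray  # (H, W, 3) uint8
    region_mask: np.ndarray  # (H, W) uint8, codes above
    label: int
    mpp: float = 0.5
    slide_id: str = "synthetic"


def _stamp_disks(img: np.ndarray, mask_region: np.ndarray, centers: np.ndarray,
                 radius: int, color: np.ndarray, rng: np.random.Generator) -> None:
    """Paint small filled disks at ``centers`` (only inside mask_region)."""
    h, w = mask_region.shape
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    stamp = (yy ** 2 + xx ** 2) <= radius ** 2
    for cy, cx in centers:
        y0, y1 = cy - radius, cy + radius + 1
        x0, x1 = cx - radius, cx + radius + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            continue
        sub = stamp & mask_region[y0:y1, x0:x1]
        jitter = rng.integers(-15, 15, size=3)
        img[y0:y1, x0:x1][sub] = np.clip(color + jitter, 0, 255).astype(np.uint8)


def _stroke_texture(shape: tuple[int, int], base: np.ndarray, theta: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Pink oriented-stroke texture: sinusoidal stripes along angle theta."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    phase = (x * np.cos(theta) + y * np.sin(theta)) * (2 * np.pi / 24.0)
    stripes = (np.sin(phase) * 18.0)[..., None]
    noise = rng.normal(0, 6.0, size=(h, w, 3))
    return np.clip(base + stripes + noise, 0, 255)


def generate_slide(label: int, size: int = 1792, seed: int = 0,
                   patch_size: int = 448, mpp: float = 0.5,
                   slide_id: str | None = None) -> SyntheticSlide:
    """Render a square toy slide of side ``size`` pixels.

    Positive slides (``label=1``) contain at least one inflamed-stroma
    region whose connected area is at least one patch footprint; negative
    slides contain none. Background pixels are near-white (all channels
    >= 235 before noise).
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if size < 2 * patch_size:
        raise ValueError(f"size must be at least 2x patch size ({2 * patch_size})")
    rng = np.random.default_rng(seed)
    h = w = size
    mask = np.full((h, w), BACKGROUND, dtype=np.uint8)

    yy, xx = np.mgrid[0:h, 0:w]

    def add_disk_region(code: int, radius: int) -> None:
        cy = rng.integers(radius, h - radius)
        cx = rng.integers(radius, w - radius)
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = code

    # paint stroma then tumor, inflamed last so it is never overwritten;
    # bulk-region radii scale with the slide so layouts look alike at any size
    for _ in range(rng.integers(2, 4)):
        add_disk_region(PLAIN_STROMA, int(rng.integers(size // 6, size // 3)))
    for _ in range(rng.integers(2, 4)):
        add_disk_region(TUMOR, int(rng.integers(size // 6, size // 3)))
    if label == 1:
        # one or two compact regions, each a little over one patch footprint:
        # the discriminative tissue occupies a small fraction of the slide,
        # as inflamed stroma does in a real section
        min_r = int(np.ceil(patch_size / np.sqrt(np.pi))) + patch_size // 16
        for _ in range(rng.integers(1, 3)):
            add_disk_region(INFLAMED_STROMA,
                            int(rng.integers(min_r, min_r + patch_size // 4)))

    # ---- render textures -------------------------------------------------
    img = rng.integers(235, 256, size=(h, w, 3)).astype(np.float64)  # background

    pink = np.array([231.0, 156.0, 178.0])
    violet = np.array([168.0, 122.0, 186.0])
    nucleus_purple = np.array([94.0, 44.0, 118.0])
    lymphocyte_blue = np.array([28.0, 36.0, 140.0])

    stroma_any = (mask == PLAIN_STROMA) | (mask == INFLAMED_STROMA)
    if stroma_any.any():
        tex = _stroke_texture((h, w), pink, rng.uniform(0, np.pi), rng)
        img[stroma_any] = tex[stroma_any]
    def region_centers(region: np.ndarray, per_pixels: int) -> np.ndarray:
        idx = np.flatnonzero(region.ravel())
        n = idx.size // per_pixels
        chosen = rng.choice(idx, size=n, replace=False)
        return np.column_stack(np.unravel_index(chosen, region.shape))

    tumor = mask == TUMOR
    if tumor.any():
        img[tumor] = np.clip(violet + rng.normal(0, 8.0, size=(h, w, 3)), 0, 255)[tumor]
        _stamp_disks(img, tumor, region_centers(tumor, 260), radius=5,
                     color=nucleus_purple, rng=rng)
    inflamed = mask == INFLAMED_STROMA
    if inflamed.any():
        # dense enough that the infiltrate dominates the patch's color
        # statistics, as a brisk lymphocytic infiltrate does at low power
        _stamp_disks(img, inflamed, region_centers(inflamed, 55), radius=3,
                     color=lymphocyte_blue, rng=rng)

    return SyntheticSlide(
        image=img.astype(np.uint8),
        region_mask=mask,
        label=int(label),
        mpp=mpp,
        slide_id=slide_id or f"synth_{label}_{seed}",
    )


def generate_stain_matrix(seed: int = 0, scale: float = 0.05) -> np.ndarray:
    """An H&E-like stain matrix: the classical vectors plus lab-to-lab jitter.

    Gaussian perturbation of the canonical optical-density vectors,
    redrawn (sub-seeded) until the chromatic identity of the stains is
    preserved — real staining variation never makes hematoxylin look like
    eosin. Rows are unit-norm, hematoxylin first.
    """
    from .stain import CANONICAL_EOSIN, CANONICAL_HEMATOXYLIN, \
        _order_hematoxylin_first

    base = np.vstack([CANONICAL_HEMATOXYLIN, CANONICAL_EOSIN])
    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        S = np.abs(base + rng.normal(0, scale, size=(2, 3)))
        S = S / np.linalg.norm(S, axis=1, keepdims=True)
        if np.array_equal(_order_hematoxylin_first(S), S):
            return S
    raise RuntimeError("could not draw an identity-preserving stain matrix")


def generate_concentration_field(seed: int = 0, shape: tuple = (96, 96),
                                 pure_fraction: float = 1 / 3) -> np.ndarray:
    """Sparse two-stain concentration field (H, E channels last).

    Gamma-distributed concentrations with a ``pure_fraction`` of pixels
    dominated by each single stain (nuclei are mostly hematoxylin, stroma
    mostly eosin); the remainder mixed. The pure pixels make the stain
    matrix identifiable, as in real tissue.
    """
    rng = np.random.default_rng(seed)
    c = rng.gamma(2.0, 0.5, size=tuple(shape) + (2,))
    u = rng.random(shape)
    c[u < pure_fraction, 1] *= 0.05
    c[u > 1 - pure_fraction, 0] *= 0.05
    return c


def generate_he_image(seed: int = 0, shape: tuple = (96, 96),
                      stain_matrix: np.ndarray | None = None):
    """Render a synthetic H&E patch from a known stain model.

    Returns ``(image, stain_matrix, concentrations)`` — the ground truth
    the stain-separation recovery tests compare against.
    """
    from .stain import render_from_model

    if stain_matrix is None:
        stain_matrix = generate_stain_matrix(seed)
    conc = generate_concentration_field(seed, shape)
    return render_from_model(conc, stain_matrix), stain_matrix, conc


@dataclass
class SyntheticCohort:
    """Per-patient covariates and slide assignments with known generating model."""

    patients: pd.DataFrame  # patient_id, age, gender, pT_stage, LVI, grade, label
    slides: pd.DataFrame  # slide_id, patient_id, label
    coefficients: np.ndarray = field(default=None)  # (intercept, age, gender, pT, LVI, grade)
    covariate_names: tuple = COVARIATE_NAMES


def _coef_vector(coefficients) -> np.ndarray:
    """Accept a full (intercept + 5) vector or a sparse name->value mapping."""
    if isinstance(coefficients, dict):
        beta = np.zeros(len(COVARIATE_NAMES) + 1)
        for key, val in coefficients.items():
            if key == "intercept":
                beta[0] = val
            elif key in COVARIATE_NAMES:
                beta[1 + COVARIATE_NAMES.index(key)] = val
            else:
                raise ValueError(f"unknown covariate {key!r}")
        return beta
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (len(COVARIATE_NAMES) + 1,):
        raise ValueError(
            f"coefficient vector must have length {len(COVARIATE_NAMES) + 1} "
            "(intercept + covariates)"
        )
    return beta


def generate_cohort(n_patients: int, coefficients=None, seed: int = 0,
                    lvi_rate: float = 0.4, male_rate: float = 0.75,
                    high_grade_rate: float = 0.93,
                    pt_probs: tuple = (0.35, 0.45, 0.20)) -> SyntheticCohort:
    """Draw a synthetic clinical cohort with labels from a logistic model.

    Covariate marginals default to frequencies typical of muscle-invasive
    bladder cancer series (~40% LVI-positive, ~75% male, predominantly
    high-grade, pT3 the modal stage). ``coefficients`` is either a
    6-vector (intercept, age, gender, pT_stage, LVI, grade) on the logit
    scale or a mapping from covariate name (or "intercept") to value;
    missing entries default to 0. Each patient receives 1–4 slides sharing
    the patient's label.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if n_patients < 20:
        warnings.warn("n_patients < 20: coefficient recovery will be unreliable",
                      stacklevel=2)
    beta = _coef_vector(coefficients if coefficients is not None else {})
    rng = np.random.default_rng(seed)

    age = np.clip(np.round(rng.normal(68, 10, n_patients)), 30, 90).astype(int)
    gender = (rng.random(n_patients) < male_rate).astype(int)
    pt = rng.choice([2, 3, 4], size=n_patients, p=np.asarray(pt_probs) / np.sum(pt_probs))
    lvi = (rng.random(n_patients) < lvi_rate).astype(int)
    grade = (rng.random(n_patients) < high_grade_rate).astype(int)

    design = np.column_stack([np.ones(n_patients), age, gender, pt, lvi, grade])
    p = 1.0 / (1.0 + np.exp(-design @ beta))
    label = (rng.random(n_patients) < p).astype(int)

    patient_id = np.array([f"pt_{i:04d}" for i in range(n_patients)])
    patients = pd.DataFrame({
        "patient_id": patient_id, "age": age, "gender": gender,
        "pT_stage": pt, "LVI": lvi, "grade": grade, "label": label,
    })

    n_slides = rng.integers(1, 5, size=n_patients)
    rows = []
    for pid, lab, k in zip(patient_id, label, n_slides):
        for j in range(k):
            rows.append({"slide_id": f"{pid}_s{j}", "patient_id": pid, "label": int(lab)})
    slides = pd.DataFrame(rows)
    return SyntheticCohort(patients=patients, slides=slides, coefficients=beta)
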