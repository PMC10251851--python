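"""Slide preprocessing: foreground segmentation, fixed-size patch tiling
with coordinate bookkeeping, and blank-patch filtering.

Foreground is found by Otsu thresholding (maximal between-class variance)
of the HSV saturation channel on a downsampled thumbnail — tissue is
chromatic while the glass background is near-achromatic. Patches of
448x448 pixels at a target resolution of 0.5 microns per pixel (20x) are
cropped on a non-overlapping grid restricted to the segmented foreground,
and patches whose background-pixel fraction exceeds 80% are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import median_filter
from skimage.color import rgb2gray, rgb2hsv
from skimage.transform import resize

DEFAULT_PATCH_SIZE = 448
DEFAULT_TARGET_MPP = 0.5


@dataclass
class SlideImage:
    """An RGB slide held in memory with its base-level resolution.

    ``mpp`` is microns per pixel at the base level (0.5 corresponds to the
    usual 20x scan).
    """

    image: np.ndarray  # (H, W, 3) uint8
    mpp: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @classmethod
    def from_file(cls, path, mpp: float = DEFAULT_TARGET_MPP,
                  slide_id: str | None = None) -> "SlideImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(image=arr, mpp=mpp, slide_id=slide_id or path.stem)


@dataclass
class ForegroundMask:
    """Binary tissue mask at ``downsample`` times lower resolution."""

    mask: np.ndarray  # (H//ds, W//ds) bool
    downsample: int
    otsu_threshold: float


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is attempted on a (near-)constant channel."""


def otsu_threshold_from_histogram(counts, bin_centers) -> float:
    """Otsu's threshold on a precomputed histogram.

    Scans every bin center t as a candidate cut (class 0: values <= t,
    class 1: values > t) and returns the t maximizing the between-class
    variance  sigma_b^2(t) = w0(t) w1(t) (mu0(t) - mu1(t))^2 ; the first
    maximizer wins on ties. Implemented with cumulative sums; equivalent
    to the exhaustive per-threshold scan.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    if counts.shape != centers.shape or counts.ndim != 1:
        raise ValueError("counts and bin_centers must be aligned 1-D arrays")
    total = counts.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "channel histogram is concentrated in a single bin; "
            "Otsu between-class variance is undefined"
        )
    w0 = np.cumsum(counts) / total
    w1 = 1.0 - w0
    m0 = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / np.cumsum(counts)
        mu1 = (m0[-1] - m0) / (total - np.cumsum(counts))
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # a cut through an empty bin yields the same partition as its left
    # neighbour; keep one representative per partition so plateau ties
    # resolve to the first (lowest) threshold
    sigma_b[counts == 0] = -np.inf
    # first maximizer within a relative tolerance: exact mathematical ties
    # (empty-bin plateaus) must not be broken by round-off in either
    # direction
    peak = sigma_b.max()
    winners = np.flatnonzero(sigma_b >= peak - 1e-10 * abs(peak))
    return float(centers[int(winners[0])])


def otsu_threshold(values, nbins: int = 256) -> float:
    """Otsu's threshold for a sample of channel values."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    return otsu_threshold_from_histogram(counts, centers)


def segment_foreground(slide: SlideImage, downsample: int = 32,
                       nbins: int = 256) -> ForegroundMask:
    """Otsu-based tissue segmentation on a downsampled thumbnail.

    The saturation channel of HSV (after a 3x3 median filter) is
    thresholded; pixels above the threshold are foreground.
    """
    h, w = slide.shape
    th, tw = max(1, h // downsample), max(1, w // downsample)
    thumb = resize(slide.image, (th, tw), order=1, preserve_range=True,
                   anti_aliasing=True).astype(np.uint8)
    sat = rgb2hsv(thumb)[..., 1]
    sat = median_filter(sat, size=3)
    thr = otsu_threshold(sat, nbins=nbins)
    return ForegroundMask(mask=sat > thr, downsample=downsample, otsu_threshold=thr)


@dataclass
class TileGrid:
    """Ordered patch coordinates (0-based, half-open) in base-level pixels.

    Each entry covers [x, x+w) x [y, y+h) at the slide's base level; after
    optional resampling every patch is delivered as patch_size x patch_size
    at target_mpp. Ordering is row-major (y, then x).
    """

    entries: pd.DataFrame  # columns slide_id, x, y, w, h, level
    patch_size: int = DEFAULT_PATCH_SIZE
    target_mpp: float = DEFAULT_TARGET_MPP

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coords(self) -> np.ndarray:
        return self.entries[["x", "y"]].to_numpy()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, patch_size: int = DEFAULT_PATCH_SIZE,
                 target_mpp: float = DEFAULT_TARGET_MPP) -> "TileGrid":
        return cls(entries=pd.read_csv(path), patch_size=patch_size,
                   target_mpp=target_mpp)


def foreground_fraction(mask: ForegroundMask, x: int, y: int, w: int, h: int) -> float:
    """Fraction of a base-level footprint covered by the (downsampled) mask."""
    ds = mask.downsample
    block = mask.mask[y // ds:(y + h) // ds, x // ds:(x + w) // ds]
    return float(block.mean()) if block.size else 0.0


def tile_slide(slide: SlideImage, mask: ForegroundMask | None = None,
               patch_size: int = DEFAULT_PATCH_SIZE,
               target_mpp: float = DEFAULT_TARGET_MPP,
               min_foreground: float = 0.5) -> TileGrid:
    """Non-overlapping patch grid over the segmented foreground.

    The stride equals the patch footprint (no overlap); partial edge
    patches are dropped. A patch is emitted iff at least ``min_foreground``
    of its footprint is tissue (always emitted when ``mask`` is None).
    When slide resolution differs from ``target_mpp``, footprints are
    scaled by target_mpp / slide.mpp and patches are later resampled.
    """
    if target_mpp < slide.mpp / 8:
        raise ValueError("refusing to upsample beyond 8x (target_mpp too small)")
    h, w = slide.shape
    foot = int(round(patch_size * target_mpp / slide.mpp))
    rows = []
    for y in range(0, h - foot + 1, foot):
        for x in range(0, w - foot + 1, foot):
            if mask is not None and foreground_fraction(mask, x, y, foot, foot) < min_foreground:
                continue
            rows.append({"slide_id": slide.slide_id, "x": x, "y": y,
                         "w": foot, "h": foot, "level": 0})
    entries = pd.DataFrame(rows, columns=["slide_id", "x", "y", "w", "h", "level"])
    return TileGrid(entries=entries, patch_size=patch_size, target_mpp=target_mpp)


def read_patch(slide: SlideImage, x: int, y: int, w: int, h: int,
               patch_size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Extract one patch, bilinearly resampled to patch_size if needed."""
    crop = slide.image[y:y + h, x:x + w]
    if crop.shape[:2] != (h, w):
        raise ValueError("patch footprint outside slide bounds")
    if (h, w) != (patch_size, patch_size):
        crop = resize(crop, (patch_size, patch_size), order=1,
                      preserve_range=True).astype(np.uint8)
    return crop


def iter_patches(slide: SlideImage, grid: TileGrid):
    """Yield (entry, patch) pairs in grid order."""
    for entry in grid.entries.itertuples(index=False):
        yield entry, read_patch(slide, entry.x, entry.y, entry.w, entry.h,
                                grid.patch_size)


def is_background(patch: np.ndarray, background_fraction_threshold: float = 0.8,
                  gray_cutoff: float = 220.0, sat_cutoff: float = 0.05) -> bool:
    """True (exclude) iff the background-pixel fraction strictly exceeds the
    threshold.

    A pixel counts as background when its grayscale intensity is >= 220/255
    or its HSV saturation is <= 0.05. The inequality on the fraction is
    strict: a patch with exactly 80% background is kept.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3 or patch.dtype != np.uint8:
        raise ValueError("patch must be 8-bit RGB (H, W, 3)")
    gray = rgb2gray(patch) * 255.0
    sat = rgb2hsv(patch)[..., 1]
    frac = float(((gray >= gray_cutoff) | (sat <= sat_cutoff)).mean())
    return frac > background_fraction_threshold
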