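"""Attention heatmaps: percentile normalization of per-patch attention and
diverging-colormap overlays on the slide.

Raw attention weights live on wildly different scales between slides (they
sum to one over a variable number of patches), so for display each patch
is mapped to its percentile rank within the slide and rescaled to [0, 1]:
1 = strongest positive evidence (red), 0 = weakest (blue). The overlay
alpha-blends the colormap over the slide so the underlying histology stays
visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.transform import resize

from .preprocessing import SlideImage, TileGrid

# blue -> white -> red ramp control points (bit-reproducible rendering)
_CMAP_POINTS = np.array([[0.0, 0.0, 255.0],
                         [255.0, 255.0, 255.0],
                         [255.0, 0.0, 0.0]])


def normalize_attention(raw, method: str = "percentile") -> np.ndarray:
    """Map raw attention scores to [0, 1].

    ``percentile`` (default): each score becomes the fraction of patches
    with strictly smaller raw score plus half its tie fraction, then
    min-max rescaled so min = 0 and max = 1; invariant under any strictly
    monotone transform of the raw scores. ``minmax``: plain linear
    rescaling. Constant input maps to all 0.5.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 1 or raw.size < 1:
        raise ValueError("raw scores must be a non-empty vector")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be finite")
    if raw.min() == raw.max():
        return np.full(raw.shape, 0.5)
    if method == "percentile":
        vals = (rankdata(raw, method="average") - 0.5) / raw.size
    elif method == "minmax":
        vals = raw
    else:
        raise ValueError(f"unknown method {method!r}")
    return (vals - vals.min()) / (vals.max() - vals.min())


@dataclass
class AttentionMap:
    """Normalized per-patch attention with its tile coordinates."""

    slide_id: str
    coords: np.ndarray  # (N, 2) base-level (x, y)
    raw: np.ndarray  # (N,)
    normalized: np.ndarray = field(default=None)
    patch_w: int = 448
    patch_h: int = 448

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.coords.shape != (self.raw.size, 2):
            raise ValueError("coords and raw scores must align")
        if self.normalized is None:
            self.normalized = normalize_attention(self.raw)

    @property
    def is_constant(self) -> bool:
        return bool(self.raw.min() == self.raw.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slide_id": self.slide_id, "x": self.coords[:, 0],
            "y": self.coords[:, 1], "raw_score": self.raw,
            "normalized_score": self.normalized,
        })

    @classmethod
    def from_grid(cls, grid: TileGrid, raw, slide_id: str | None = None,
                  method: str = "percentile") -> "AttentionMap":
        e = grid.entries
        return cls(slide_id=slide_id or str(e["slide_id"].iloc[0]),
                   coords=e[["x", "y"]].to_numpy(), raw=np.asarray(raw),
                   normalized=normalize_attention(raw, method=method),
                   patch_w=int(e["w"].iloc[0]), patch_h=int(e["h"].iloc[0]))


def diverging_colors(values) -> np.ndarray:
    """Blue-white-red diverging colormap; values in [0, 1] -> RGB floats."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    t = np.where(v < 0.5, v * 2.0, (v - 0.5) * 2.0)[..., None]
    low = np.where(v[..., None] < 0.5, _CMAP_POINTS[0], _CMAP_POINTS[1])
    high = np.where(v[..., None] < 0.5, _CMAP_POINTS[1], _CMAP_POINTS[2])
    return low + t * (high - low)


def render_heatmap(slide: SlideImage, amap: AttentionMap, alpha: float = 0.6,
                   downsample: int = 1) -> np.ndarray:
    """Alpha-blend the diverging colormap over each patch footprint.

    out = alpha * color + (1 - alpha) * base inside footprints; pixels not
    covered by any patch are returned unchanged. Rendering happens at
    ``downsample`` times lower resolution.
    """
    h, w = slide.shape
    bad = [i for i, (x, y) in enumerate(amap.coords)
           if x < 0 or y < 0 or x + amap.patch_w > w or y + amap.patch_h > h]
    if bad:
        raise ValueError(f"patch coords outside slide bounds at indices {bad}")
    if downsample > 1:
        base = resize(slide.image, (h // downsample, w // downsample), order=1,
                      preserve_range=True, anti_aliasing=True)
    else:
        base = slide.image.astype(np.float64)
    out = base.copy()
    colors = diverging_colors(amap.normalized)
    for (x, y), color in zip(amap.coords, colors):
        x0, y0 = x // downsample, y // downsample
        x1 = (x + amap.patch_w) // downsample
        y1 = (y + amap.patch_h) // downsample
        out[y0:y1, x0:x1] = alpha * color + (1 - alpha) * out[y0:y1, x0:x1]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def top_scoring_patches(amap: AttentionMap, k: int = 15) -> pd.DataFrame:
    """The k highest-attention patches, descending; ties by (y, x) ascending."""
    if k <= 0:
        raise ValueError("k must be positive")
    order = np.lexsort((amap.coords[:, 0], amap.coords[:, 1], -amap.raw))
    order = order[:min(k, amap.raw.size)]
    return amap.to_frame().iloc[order].reset_index(drop=True)
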