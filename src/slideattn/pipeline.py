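"""End-to-end orchestration: slide image -> tissue tiles -> stain-normalized
patches -> feature bag.

This is the glue the CLI and the synthetic-pipeline experiments use; every
step delegates to the dedicated module. One stain model is estimated per
slide (on its tissue pixels) and every kept patch is mapped to the shared
reference appearance before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bags import FeatureBag
from .features import extract_features
from .preprocessing import (SlideImage, TileGrid, is_background,
                            iter_patches, segment_foreground, tile_slide)
from .stain import StainModel, default_reference_model, estimate_stain_model, \
    normalize_to_reference
from .synthetic import INFLAMED_STROMA, SyntheticSlide


@dataclass
class SlideBagResult:
    """A built bag together with the grid it came from."""

    bag: FeatureBag
    grid: TileGrid
    kept: np.ndarray  # indices of grid entries that survived the blank filter
    stain_model: StainModel | None = None


def build_bag(slide: SlideImage, patient_id: str, label: int, encoder,
              patch_size: int = 448, target_mpp: float | None = None,
              reference: StainModel | None = None, normalize: bool = True,
              min_foreground: float = 0.5, bg_threshold: float = 0.8,
              stain_seed: int = 0, witness=None) -> SlideBagResult:
    """Tile one slide, filter blanks, normalize stains, and encode patches.

    ``witness`` may be a callable mapping a grid entry to a bool flag
    (used with synthetic slides where ground truth is known).
    """
    target_mpp = target_mpp if target_mpp is not None else slide.mpp
    mask = segment_foreground(slide)
    grid = tile_slide(slide, mask, patch_size=patch_size,
                      target_mpp=target_mpp, min_foreground=min_foreground)
    if len(grid) == 0:
        raise ValueError(f"no foreground patches on slide {slide.slide_id}")

    source_model = None
    if normalize:
        reference = reference or default_reference_model()
        source_model = estimate_stain_model(slide.image, seed=stain_seed)

    patches, kept, flags = [], [], []
    for i, (entry, patch) in enumerate(iter_patches(slide, grid)):
        if is_background(patch, background_fraction_threshold=bg_threshold):
            continue
        if normalize:
            patch = normalize_to_reference(patch, reference, source_model)
        patches.append(patch)
        kept.append(i)
        if witness is not None:
            flags.append(bool(witness(entry)))
    if not patches:
        raise ValueError(f"all patches of slide {slide.slide_id} were blank")

    feats = extract_features(patches, encoder)
    coords = grid.entries.iloc[kept][["x", "y"]].to_numpy()
    bag = FeatureBag(slide_id=slide.slide_id, patient_id=patient_id,
                     label=label, features=feats, coords=coords,
                     witness=np.asarray(flags) if witness is not None else None)
    return SlideBagResult(bag=bag, grid=grid, kept=np.asarray(kept),
                          stain_model=source_model)


def region_fraction(slide: SyntheticSlide, entry, region: int = INFLAMED_STROMA) -> float:
    """Fraction of a grid entry's footprint covered by a region-mask class."""
    block = slide.region_mask[entry.y:entry.y + entry.h, entry.x:entry.x + entry.w]
    return float((block == region).mean())


def synthetic_witness(slide: SyntheticSlide, min_fraction: float = 0.05,
                      region: int = INFLAMED_STROMA):
    """Witness rule for synthetic slides: footprint >= min_fraction inflamed."""
    def _flag(entry) -> bool:
        return region_fraction(slide, entry, region) >= min_fraction
    return _flag


def bag_from_synthetic_slide(slide: SyntheticSlide, patient_id: str, encoder,
                             **kwargs) -> SlideBagResult:
    """Build a bag from a synthetic slide, recording ground-truth witnesses."""
    image = SlideImage(image=slide.image, mpp=slide.mpp, slide_id=slide.slide_id)
    return build_bag(image, patient_id=patient_id, label=slide.label,
                     encoder=encoder, witness=synthetic_witness(slide), **kwargs)
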