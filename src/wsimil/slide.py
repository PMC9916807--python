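"""Slide reading, foreground segmentation, and patch tiling.

Slides are accessed through a thin reader contract (:class:`SlideReader`)
so pyramidal formats can be plugged in; at desk scale the bundled readers
cover in-memory arrays and tiled TIFFs.

Foreground detection follows standard computational-pathology practice for
stained slides: work on the HSV saturation channel (glass is bright and
unsaturated, tissue is saturated), median-blur it, threshold with Otsu's
method, then clean up with morphological closing, hole filling and a
minimum-area filter.  Tiling lays a non-overlapping patch grid anchored at
the slide origin and keeps every patch whose foreground fraction reaches a
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import tifffile
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, footprint_rectangle, remove_small_objects
from skimage.transform import resize

from .bags import TileSet

__all__ = [
    "SlideReader",
    "ArraySlide",
    "TiffSlide",
    "open_slide",
    "segment_foreground",
    "tile",
]


@runtime_checkable
class SlideReader(Protocol):
    """Minimal reader contract: dimensions and region reads at level 0."""

    slide_id: str

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """RGB uint8 array of shape (h, w, 3) at level-0 coordinates."""

    def read_image(self) -> np.ndarray:
        """Whole level-0 image as RGB uint8 (desk scale only)."""


class ArraySlide:
    """A slide backed by an in-memory RGB array."""

    def __init__(self, image: np.ndarray, slide_id: str = "array"):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
            raise IOError("slide image must be a non-empty H x W x 3 array")
        self._img = image
        self.slide_id = slide_id

    @property
    def dimensions(self) -> tuple[int, int]:
        h, w = self._img.shape[:2]
        return (w, h)

    def read_region(self, x, y, w, h) -> np.ndarray:
        W, H = self.dimensions
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise IOError(f"read_region box ({x},{y},{w},{h}) outside slide bounds")
        return self._img[y : y + h, x : x + w]

    def read_image(self) -> np.ndarray:
        return self._img


class TiffSlide(ArraySlide):
    """A slide backed by a (tiled) TIFF file, loaded fully at desk scale."""

    def __init__(self, path: str | Path):
        path = Path(path)
        try:
            img = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - passthrough
            raise IOError(f"cannot read slide {path}: {exc}") from exc
        super().__init__(img, slide_id=path.stem)


def open_slide(source) -> SlideReader:
    """Open a slide from a path, array, or pass through an existing reader."""
    if isinstance(source, (str, Path)):
        return TiffSlide(source)
    if isinstance(source, np.ndarray):
        return ArraySlide(source)
    if isinstance(source, SlideReader):
        return source
    raise IOError(f"cannot open slide from {type(source).__name__}")


def segment_foreground(
    slide,
    max_mask_pixels: int = 4_000_000,
    median_size: int = 5,
    closing_radius: int = 2,
    min_area: int = 64,
) -> tuple[np.ndarray, int]:
    """Segment tissue from background; return ``(mask, downsample)``.

    The mask is computed at an integer downsample chosen so that it holds at
    most ``max_mask_pixels`` pixels.  Background (bright, unsaturated glass)
    is False; tissue is True.  An all-background slide yields an empty mask
    with a warning rather than an error.
    """
    reader = open_slide(slide)
    img = reader.read_image()
    h, w = img.shape[:2]
    ds = 1
    while (h // ds) * (w // ds) > max_mask_pixels:
        ds *= 2
    if ds > 1:
        img = resize(img, (h // ds, w // ds), anti_aliasing=True, preserve_range=True)
    sat = rgb2hsv(np.asarray(img, dtype=np.uint8))[:, :, 1]
    sat = median_filter(sat, footprint_rectangle((median_size, median_size)))
    if np.ptp(sat) < 0.05:
        warnings.warn(f"slide {reader.slide_id}: no tissue found (uniform saturation)")
        return np.zeros(sat.shape, dtype=bool), ds
    mask = sat > threshold_otsu(sat)
    mask = closing(mask, disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        warnings.warn(f"slide {reader.slide_id}: empty foreground mask")
    return mask, ds


def tile(
    slide_dims: tuple[int, int],
    mask: np.ndarray,
    patch_size: int = 256,
    min_foreground_fraction: float = 0.5,
    mask_downsample: int = 1,
    slide_id: str = "slide",
) -> TileSet:
    """Grid-tile the slide, keeping patches with enough foreground.

    The grid is anchored at (0, 0) with stride ``patch_size`` (no overlap);
    only fully in-bounds patches are considered.  A patch is retained when
    the mean of ``mask`` over its footprint is >= ``min_foreground_fraction``.
    Coordinates come out sorted row-major (y, then x).
    """
    if patch_size < 32:
        raise ValueError("patch_size must be >= 32")
    W, H = slide_dims
    if patch_size > W or patch_size > H:
        warnings.warn(f"patch_size {patch_size} exceeds slide dims {slide_dims}; empty TileSet")
        return TileSet(slide_id=slide_id, patch_size=patch_size,
                       coords=np.empty((0, 2), dtype=np.int64),
                       mask_summary=np.empty(0))
    mask = np.asarray(mask, dtype=bool)
    coords, fracs = [], []
    for y in range(0, H - patch_size + 1, patch_size):
        for x in range(0, W - patch_size + 1, patch_size):
            my0 = y // mask_downsample
            mx0 = x // mask_downsample
            my1 = max(my0 + 1, math.ceil((y + patch_size) / mask_downsample))
            mx1 = max(mx0 + 1, math.ceil((x + patch_size) / mask_downsample))
            frac = float(mask[my0:my1, mx0:mx1].mean()) if mask.size else 0.0
            if frac >= min_foreground_fraction:
                coords.append((x, y))
                fracs.append(frac)
    return TileSet(
        slide_id=slide_id,
        patch_size=patch_size,
        coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
        mask_summary=np.asarray(fracs, dtype=float),
    )
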