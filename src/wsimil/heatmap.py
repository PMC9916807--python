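"""Attention heatmaps: paint per-patch attention over the slide.

Attention scores are min-max normalized per slide to [0, 1] and each patch
footprint is filled with a diverging colormap (red = strongly attended,
blue = weakly attended), alpha-blended over the slide image (or a white
canvas when only dimensions are given).  Non-tissue regions are untouched.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

from .bags import TileSet
from .slide import open_slide

__all__ = ["HeatmapSpec", "render_heatmap", "write_heatmap_outputs", "normalize_attention"]


@dataclass
class HeatmapSpec:
    class_index: int = 1
    colormap: str = "coolwarm"
    alpha_blend: float = 0.5
    downsample: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.alpha_blend <= 1.0:
            raise ValueError("alpha_blend must lie in [0, 1]")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


def normalize_attention(attention_row: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant input maps to all 0.5 (warned)."""
    a = np.asarray(attention_row, dtype=float).ravel()
    span = a.max() - a.min()
    if span == 0:
        warnings.warn("constant attention: normalized scores set to 0.5")
        return np.full_like(a, 0.5)
    return (a - a.min()) / span


def render_heatmap(slide_or_dims, tileset: TileSet, attention_row: np.ndarray,
                   spec: HeatmapSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(RGB uint8 overlay, normalized per-patch scores)``.

    ``slide_or_dims`` is either a slide (reader/array/path) or a
    ``(width, height)`` tuple, in which case a white canvas is used.
    """
    spec = spec or HeatmapSpec()
    spec.validate()
    attention_row = np.asarray(attention_row, dtype=float).ravel()
    if attention_row.size != len(tileset):
        raise ValueError("attention length must equal the number of tiles")
    if isinstance(slide_or_dims, tuple):
        W, H = slide_or_dims
        base = np.full((H // spec.downsample, W // spec.downsample, 3), 255.0)
    else:
        reader = open_slide(slide_or_dims)
        W, H = reader.dimensions
        img = reader.read_image().astype(float)
        if spec.downsample > 1:
            img = img[:: spec.downsample, :: spec.downsample]
        base = img
    norm = normalize_attention(attention_row)
    cmap = matplotlib.colormaps[spec.colormap]
    ds, ps, ab = spec.downsample, tileset.patch_size, spec.alpha_blend
    out = base.copy()
    for (x, y), score in zip(tileset.coords, norm):
        x0, y0 = int(x) // ds, int(y) // ds
        x1, y1 = min(out.shape[1], (int(x) + ps) // ds), min(out.shape[0], (int(y) + ps) // ds)
        color = np.array(cmap(float(score))[:3]) * 255.0
        out[y0:y1, x0:x1] = (1 - ab) * out[y0:y1, x0:x1] + ab * color
    return np.clip(out, 0, 255).astype(np.uint8), norm


def write_heatmap_outputs(image: np.ndarray, tileset: TileSet,
                          attention_row: np.ndarray, norm: np.ndarray,
                          png_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write the overlay PNG and a per-patch attention CSV."""
    import matplotlib.image

    matplotlib.image.imsave(str(png_path), image)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["x", "y", "raw_attention", "normalized_attention"])
            for (x, y), raw, nv in zip(tileset.coords, np.ravel(attention_row), norm):
                wr.writerow([int(x), int(y), float(raw), float(nv)])
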