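"""Synthetic fixtures: Gaussian MIL feature bags and toy slide images.

Two generators stand in for real whole-slide data so every pipeline stage
can be exercised with known ground truth:

* :func:`simulate_bags` draws bags of instance embeddings from a two-component
  isotropic Gaussian mixture.  Positive bags contain a minority of "signal"
  instances whose mean is shifted from the background mean; negative bags
  contain background instances only.  Per-instance signal flags are returned
  for attention-recovery checks and must never be used as training input.
* :func:`render_toy_slide` paints rectangular "tissue" blobs on a bright
  glass-like background, returning the image together with the exact
  foreground mask, so segmentation and tiling can be scored against truth.

Each bag (and each slide) draws from its own RNG substream spawned from the
global seed, so enlarging a dataset never reshuffles earlier members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .bags import FeatureBag

__all__ = [
    "BagSimSpec",
    "ToySlideSpec",
    "SimulatedBags",
    "simulate_bags",
    "render_toy_slide",
    "write_toy_slide",
    "simulate_toy_cohort",
]

#: RGB used for painted tissue blobs: a Papanicolaou-like purple with high
#: saturation so a saturation-based foreground rule separates it from glass.
TISSUE_RGB = (148, 90, 158)
#: RGB for "lesion" blobs in positive toy-cohort slides (more red).
LESION_RGB = (190, 60, 95)


@dataclass
class BagSimSpec:
    """Study conditions for a simulated MIL dataset.

    The defaults mirror a weakly supervised slide-classification cohort:
    82% positive prevalence, 1024-dimensional instance embeddings, and bag
    sizes of 30-120 instances.  ``mu_signal`` and ``mu_background`` are
    scalar means applied isotropically to every embedding coordinate.
    """

    n_bags: int = 100
    prevalence: float = 0.82
    bag_size_range: tuple[int, int] = (30, 120)
    witness_rate: float = 0.1
    dim: int = 1024
    mu_background: float = 0.0
    mu_signal: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ValueError("bag_size_range must satisfy 1 <= min <= max")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass
class SimulatedBags:
    """Bags plus ground-truth per-instance signal flags (evaluation only)."""

    bags: list[FeatureBag]
    instance_flags: list[np.ndarray]  # bool (K,) per bag

    def __iter__(self):
        return iter(self.bags)

    def __len__(self):
        return len(self.bags)


def _positive_indices(n_bags: int, prevalence: float) -> np.ndarray:
    """Evenly spaced positive bag indices: exactly round(n * prevalence)."""
    n_pos = int(round(n_bags * prevalence))
    if n_pos == 0:
        return np.empty(0, dtype=int)
    return np.unique(np.round(np.linspace(0, n_bags - 1, n_pos)).astype(int))


def _bag_rng(seed: int, bag_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, bag_index)))


def simulate_bags(spec: BagSimSpec) -> SimulatedBags:
    """Draw a labeled MIL dataset from the Gaussian-mixture bag model.

    Exactly ``round(n_bags * prevalence)`` bags are positive.  A positive
    bag of size K carries ``ceil(witness_rate * K)`` signal instances at
    random positions; all other instances (and every instance of a negative
    bag) are background.  Instance features are i.i.d.
    ``Normal(mu * 1, sigma^2 I)`` with ``mu`` the signal or background mean.
    """
    spec.validate()
    pos = set(_positive_indices(spec.n_bags, spec.prevalence).tolist())
    bags: list[FeatureBag] = []
    flags: list[np.ndarray] = []
    lo, hi = spec.bag_size_range
    for b in range(spec.n_bags):
        rng = _bag_rng(spec.seed, b)
        k = int(rng.integers(lo, hi + 1))
        flag = np.zeros(k, dtype=bool)
        if b in pos:
            n_sig = math.ceil(spec.witness_rate * k)
            flag[rng.choice(k, size=n_sig, replace=False)] = True
        mu = np.where(flag, spec.mu_signal, spec.mu_background)[:, None]
        feats = rng.normal(loc=mu, scale=spec.sigma, size=(k, spec.dim))
        # synthetic patch grid coordinates, row-major on a 256-px grid
        g = max(1, math.ceil(math.sqrt(k)))
        idx = np.arange(k)
        coords = np.stack([(idx % g) * 256, (idx // g) * 256], axis=1)
        bags.append(
            FeatureBag(
                slide_id=f"sim_{b:05d}",
                features=feats.astype(np.float32),
                coords=coords,
                label=int(b in pos),
            )
        )
        flags.append(flag)
    return SimulatedBags(bags=bags, instance_flags=flags)


@dataclass
class ToySlideSpec:
    """A toy slide: tissue rectangles on bright background.

    ``blob_boxes`` are ``(x, y, w, h)`` rectangles in pixel coordinates that
    must lie within the image bounds.
    """

    width: int = 1024
    height: int = 1024
    background_intensity: int = 235
    blob_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    noise_sd: float = 3.0
    seed: int = 0
    blob_colors: list[tuple[int, int, int]] | None = None  # default TISSUE_RGB

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1 (zero-area image)")
        for (x, y, w, h) in self.blob_boxes:
            if w < 1 or h < 1 or x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                raise ValueError(f"blob_boxes entry {(x, y, w, h)} outside image bounds")
        if self.blob_colors is not None and len(self.blob_colors) != len(self.blob_boxes):
            raise ValueError("blob_colors must match blob_boxes in length")


def render_toy_slide(spec: ToySlideSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the toy slide; return ``(rgb uint8 image, bool foreground mask)``.

    The mask is exactly the union of ``blob_boxes``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width, 3), spec.background_intensity, dtype=float)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    colors = spec.blob_colors or [TISSUE_RGB] * len(spec.blob_boxes)
    for (x, y, w, h), color in zip(spec.blob_boxes, colors):
        img[y : y + h, x : x + w] = color
        mask[y : y + h, x : x + w] = True
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def write_toy_slide(spec: ToySlideSpec, path) -> np.ndarray:
    """Render and write the toy slide as a tiled RGB TIFF; return the mask."""
    img, mask = render_toy_slide(spec)
    tifffile.imwrite(path, img, tile=(256, 256), photometric="rgb")
    return mask


def simulate_toy_cohort(
    n_slides: int = 20,
    prevalence: float = 0.5,
    width: int = 1024,
    height: int = 1024,
    seed: int = 0,
    n_blobs_range: tuple[int, int] = (3, 6),
    blob_size_range: tuple[int, int] = (128, 320),
) -> list[tuple[ToySlideSpec, int]]:
    """Specs for a labeled cohort of toy slides for end-to-end pipeline runs.

    Positive slides carry a fraction of "lesion"-colored blobs so that a
    color-sensitive patch encoder makes the classes distinguishable; negative
    slides use the plain tissue color throughout.
    """
    pos = set(_positive_indices(n_slides, prevalence).tolist())
    cohort = []
    for s in range(n_slides):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, s)))
        n_blobs = int(rng.integers(n_blobs_range[0], n_blobs_range[1] + 1))
        boxes, colors = [], []
        label = int(s in pos)
        for j in range(n_blobs):
            w = int(rng.integers(blob_size_range[0], blob_size_range[1] + 1))
            h = int(rng.integers(blob_size_range[0], blob_size_range[1] + 1))
            x = int(rng.integers(0, width - w + 1))
            y = int(rng.integers(0, height - h + 1))
            boxes.append((x, y, w, h))
            lesion = label == 1 and (j == 0 or rng.random() < 0.4)
            colors.append(LESION_RGB if lesion else TISSUE_RGB)
        cohort.append(
            (
                ToySlideSpec(
                    width=width,
                    height=height,
                    blob_boxes=boxes,
                    blob_colors=colors,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
                label,
            )
        )
    return cohort
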