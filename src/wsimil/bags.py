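"""Feature bags and tile sets: the in-memory and on-disk units of weak supervision.

A *bag* is one slide's worth of patch embeddings plus the slide-level label;
a *tile set* is the list of foreground patch coordinates for one slide.
Bags are stored one HDF5 file per slide with datasets ``features`` (K x D,
float32) and ``coords`` (K x 2, int64, (x, y) top-left corners at level 0)
and attributes ``label`` and ``slide_id``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "FeatureBag",
    "TileSet",
    "save_bag",
    "load_bag",
    "load_bag_dir",
]


@dataclass
class TileSet:
    """Foreground patch grid for one slide.

    Coordinates are 0-based level-0 pixel positions of patch top-left
    corners; each patch covers the half-open box
    ``[x, x + patch_size) x [y, y + patch_size)``.  ``coords`` is sorted
    row-major (y, then x) and duplicate-free.  ``mask_summary`` holds the
    foreground fraction of each retained patch.
    """

    slide_id: str
    patch_size: int
    coords: np.ndarray  # (K, 2) int64, columns (x, y)
    mask_summary: np.ndarray = field(default=None)  # (K,) float
    level: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if self.mask_summary is None:
            self.mask_summary = np.ones(len(self.coords))
        self.mask_summary = np.asarray(self.mask_summary, dtype=float).ravel()
        if len(self.mask_summary) != len(self.coords):
            raise ValueError("mask_summary length must match coords")

    def __len__(self) -> int:
        return len(self.coords)

    def to_json(self) -> str:
        return json.dumps(
            {
                "slide_id": self.slide_id,
                "patch_size": int(self.patch_size),
                "level": int(self.level),
                "coords": self.coords.tolist(),
                "mask_summary": self.mask_summary.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileSet":
        d = json.loads(text)
        return cls(
            slide_id=d["slide_id"],
            patch_size=d["patch_size"],
            coords=np.asarray(d["coords"], dtype=np.int64).reshape(-1, 2),
            mask_summary=np.asarray(d["mask_summary"], dtype=float),
            level=d.get("level", 0),
        )


@dataclass
class FeatureBag:
    """One slide as a bag of patch embeddings with a slide-level label."""

    slide_id: str
    features: np.ndarray  # (K, D) float32
    coords: np.ndarray  # (K, 2) int64
    label: int = -1  # -1 = unlabeled

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a K x D matrix with K >= 1")
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.coords) != len(self.features):
            raise ValueError("coords must align row-for-row with features")
        self.label = int(self.label)

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def save_bag(bag: FeatureBag, path: str | Path) -> Path:
    """Write one bag to an HDF5 archive (``features``, ``coords``, attrs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        f.attrs["label"] = int(bag.label)
        f.attrs["slide_id"] = bag.slide_id
    return path


def load_bag(path: str | Path) -> FeatureBag:
    with h5py.File(path, "r") as f:
        return FeatureBag(
            slide_id=str(f.attrs["slide_id"]),
            features=f["features"][:],
            coords=f["coords"][:],
            label=int(f.attrs["label"]),
        )


def load_bag_dir(directory: str | Path) -> list[FeatureBag]:
    """Load every ``*.h5`` bag archive in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.h5"))
    if not paths:
        warnings.warn(f"no bag archives found in {directory}")
    return [load_bag(p) for p in paths]
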