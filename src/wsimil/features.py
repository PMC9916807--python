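"""Patch-level feature extraction behind a pluggable encoder contract.

The model consumes fixed patch embeddings ``z_k`` (1024-dimensional by
default), so the encoder is a contract rather than a fixed network: any
deterministic map from a batch of RGB patches to a ``(B, output_dim)``
float matrix qualifies.  A deep trunk such as a ResNet101 truncated at its
1024-channel stage satisfies the contract; the bundled
:func:`default_desk_encoder` is a small seeded random-projection encoder
meant for offline desk-scale runs and is NOT a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize

from .bags import FeatureBag, TileSet
from .slide import open_slide

__all__ = ["EncoderContract", "default_desk_encoder", "extract_features"]


@dataclass
class EncoderContract:
    """A named, fixed-output-dimension patch encoder.

    ``apply`` maps a batch of RGB uint8 patches ``(B, h, w, 3)`` to a
    ``(B, output_dim)`` float32 matrix; it must be deterministic and emit
    finite values only.
    """

    name: str
    output_dim: int
    apply: Callable[[np.ndarray], np.ndarray]

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        out = np.asarray(self.apply(patches), dtype=np.float32)
        if out.ndim != 2 or out.shape != (len(patches), self.output_dim):
            raise ValueError(
                f"encoder {self.name} returned shape {out.shape}, "
                f"expected ({len(patches)}, {self.output_dim})"
            )
        if not np.isfinite(out).all():
            raise ValueError(f"encoder {self.name} produced non-finite values")
        return out


def default_desk_encoder(seed: int = 0, output_dim: int = 1024, thumb: int = 16) -> EncoderContract:
    """Deterministic desk-scale encoder: thumbnail -> random projection -> tanh.

    Each patch is resized to ``thumb x thumb`` RGB, flattened, centred to
    [-1, 1], passed through a fixed Gaussian projection drawn once from
    ``seed``, and squashed with tanh.  Same seed, same weights; same patch,
    same embedding.  This is a stand-in encoder for offline tests, not a
    trained feature extractor.
    """
    rng = np.random.default_rng(seed)
    in_dim = thumb * thumb * 3
    W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(output_dim, in_dim)).astype(np.float32)

    def apply(patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        out = np.empty((len(patches), output_dim), dtype=np.float32)
        # one matrix-vector product per patch: keeps the floating-point
        # summation order fixed, so results are bit-identical across batchings
        for i, p in enumerate(patches):
            t = resize(p, (thumb, thumb, 3), anti_aliasing=True, preserve_range=True)
            flat = (t.ravel().astype(np.float32) / 127.5) - 1.0
            out[i] = np.tanh(W @ flat)
        return out

    return EncoderContract(name=f"desk(seed={seed})", output_dim=output_dim, apply=apply)


def extract_features(
    slide,
    tileset: TileSet,
    encoder: EncoderContract,
    batch_size: int = 64,
    label: int = -1,
) -> FeatureBag:
    """Encode every tile of a slide into a feature bag.

    Row ``k`` of the result is the encoder output for the patch at
    ``tileset.coords[k]``; order is preserved and the result is independent
    of ``batch_size``.
    """
    if len(tileset) == 0:
        raise ValueError("tileset is empty; nothing to extract")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    reader = open_slide(slide)
    ps = tileset.patch_size
    rows = []
    for start in range(0, len(tileset), batch_size):
        chunk = tileset.coords[start : start + batch_size]
        patches = np.empty((len(chunk), ps, ps, 3), dtype=np.uint8)
        for j, (x, y) in enumerate(chunk):
            try:
                patches[j] = reader.read_region(int(x), int(y), ps, ps)
            except Exception as exc:
                raise IOError(f"failed to read patch at ({x}, {y}): {exc}") from exc
        rows.append(encoder(patches))
    return FeatureBag(
        slide_id=tileset.slide_id,
        features=np.vstack(rows),
        coords=tileset.coords,
        label=label,
    )
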