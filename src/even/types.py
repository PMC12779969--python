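"""Core containers shared across the pipeline.

Conventions used throughout the package:

* images are 2D ``float`` arrays indexed ``[row, col]`` (row = y, col = x),
  0-based, row-major;
* a composite image of ``n_rows x n_cols`` square tiles of side ``T`` has
  shape ``(n_rows * T, n_cols * T)`` — overlap, if any, has already been
  trimmed away (``overlap_fraction`` records the acquisition overlap as
  metadata);
* intensities are unitless and expected in ``[0, 1]`` after rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np


@dataclass
class CompositeImage:
    """A stitched tile mosaic plus its grid metadata.

    Parameters
    ----------
    pixels:
        2D intensity array of shape ``(n_rows * tile_size, n_cols * tile_size)``.
    tile_size:
        Side length ``T`` of the square tiles, in pixels.
    grid:
        ``(n_rows, n_cols)`` tile counts.
    overlap_fraction:
        Fraction of the tile side shared with each neighbour during
        acquisition (metadata; the stored pixels are already abutted).
    """

    pixels: np.ndarray
    tile_size: int
    grid: tuple[int, int]
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if self.tile_size <= 0:
            raise ValueError(f"tile_size must be positive, got {self.tile_size}")
        n_rows, n_cols = self.grid
        expected = (n_rows * self.tile_size, n_cols * self.tile_size)
        if self.pixels.shape != expected:
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match "
                f"grid {self.grid} of {self.tile_size}x{self.tile_size} tiles "
                f"(expected {expected})"
            )
        if self.overlap_fraction < 0:
            raise ValueError("overlap_fraction must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CompositeImage":
        """Return a copy carrying the same grid metadata but new pixels."""
        return replace(self, pixels=pixels)


@dataclass
class MultichannelImage:
    """An ordered set of channels sharing one tile grid."""

    channels: Dict[str, CompositeImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        metas = {
            (c.shape, c.tile_size, c.grid) for c in self.channels.values()
        }
        if len(metas) > 1:
            raise ValueError("all channels must share dimensions and grid metadata")

    @property
    def channel_ids(self) -> list[str]:
        return list(self.channels)

    def grayscale_sum(self) -> np.ndarray:
        """Pixelwise sum over channels (the diagnostic grayscale image)."""
        if not self.channels:
            raise ValueError("image has no channels")
        return np.sum([c.pixels for c in self.channels.values()], axis=0)
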