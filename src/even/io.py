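"""TIFF input/output, feature tables and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CompositeImage, MultichannelImage

__all__ = [
    "RunConfig",
    "read_composite",
    "read_multichannel",
    "write_image",
    "write_features_csv",
]

#: columns of the per-image feature table, in output order
FEATURE_CSV_COLUMNS = (
    "image_id", "channel", "method", "e_edge", "p_plus",
    "tile_size", "binning", "threshold_mode", "threshold_value",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable).

    Unknown keys are rejected so a typo in a config file fails loudly
    instead of silently running with defaults.
    """

    tile_size: int = 64
    grid: tuple[int, int] | None = None
    overlap_fraction: float = 0.0
    binning: int = 1
    threshold_mode: str = "radial"
    threshold_frac: float = 0.375
    percentile_lo: float = 0.0
    percentile_hi: float = 100.0
    method_priority: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.binning < 1 or self.tile_size % self.binning:
            raise ValueError("binning must be >= 1 and divide tile_size")
        if self.threshold_mode not in ("radial", "lateral"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if not 0 <= self.percentile_lo < self.percentile_hi <= 100:
            raise ValueError("need 0 <= percentile_lo < percentile_hi <= 100")
        if self.overlap_fraction < 0:
            raise ValueError("overlap_fraction must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in data and data["grid"] is not None:
            data["grid"] = tuple(data["grid"])
        if "method_priority" in data:
            data["method_priority"] = tuple(data["method_priority"])
        return cls(**data)


def _to_float(pixels: np.ndarray) -> np.ndarray:
    """Scale integer images by their dtype maximum; pass floats through."""
    if np.issubdtype(pixels.dtype, np.integer):
        info = np.iinfo(pixels.dtype)
        return pixels.astype(float) / info.max
    return pixels.astype(float)


def _infer_grid(shape: tuple[int, int], tile_size: int) -> tuple[int, int]:
    n, m = shape
    if n % tile_size or m % tile_size:
        raise ValueError(
            f"image shape {shape} is not divisible by tile size {tile_size}"
        )
    return (n // tile_size, m // tile_size)


def read_composite(
    path: str | Path,
    tile_size: int,
    grid: tuple[int, int] | None = None,
    overlap_fraction: float = 0.0,
    page: int = 0,
) -> CompositeImage:
    """Read a grayscale 2D TIFF as a composite with grid metadata.

    8/16-bit integer data are scaled by their dtype maximum to [0, 1];
    float data are used as stored.  For a multi-page file, ``page``
    selects the channel.
    """
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[page]
    if data.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {data.shape}")
    pixels = _to_float(data)
    if grid is None:
        grid = _infer_grid(pixels.shape, tile_size)
    return CompositeImage(
        pixels=pixels, tile_size=tile_size, grid=grid,
        overlap_fraction=overlap_fraction,
    )


def read_multichannel(
    path: str | Path,
    tile_size: int,
    channel_ids: Sequence[str] | None = None,
    grid: tuple[int, int] | None = None,
    overlap_fraction: float = 0.0,
) -> MultichannelImage:
    """Read a multi-page TIFF as an ordered multichannel image."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected pages of 2D images, got shape {data.shape}")
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(data.shape[0])]
    if len(channel_ids) != data.shape[0]:
        raise ValueError(
            f"declared {len(channel_ids)} channels but file has {data.shape[0]} pages"
        )
    channels = {}
    for cid, page in zip(channel_ids, data):
        pixels = _to_float(page)
        g = grid if grid is not None else _infer_grid(pixels.shape, tile_size)
        channels[cid] = CompositeImage(
            pixels=pixels, tile_size=tile_size, grid=g,
            overlap_fraction=overlap_fraction,
        )
    return MultichannelImage(channels=channels)


def write_image(path: str | Path, image: CompositeImage | MultichannelImage) -> None:
    """Write a composite (single page) or multichannel (page per channel) TIFF."""
    if isinstance(image, MultichannelImage):
        stack = np.stack([c.pixels for c in image.channels.values()])
        tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    else:
        tifffile.imwrite(path, image.pixels.astype(np.float32),
                         photometric="minisblack")


def write_features_csv(path: str | Path, rows: Sequence[dict]) -> pd.DataFrame:
    """Write per-image feature rows in deterministic column and row order."""
    df = pd.DataFrame(list(rows), columns=list(FEATURE_CSV_COLUMNS))
    df = df.sort_values(["image_id", "channel", "method"], kind="mergesort")
    df.to_csv(path, index=False)
    return df
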