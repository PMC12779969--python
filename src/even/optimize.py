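"""Per-channel variant selection and assembly of the optimized image.

Every channel of a multichannel composite is corrected independently by
any number of methods; each variant (the raw channel always included) is
scored by the quality model, the variants are ranked, and the top variant
per channel is merged into the optimized multichannel output.  Channels
are scored strictly independently — no cross-channel balance adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import LDAModel, QualityRanking, rank_variants
from .correct import CorrectionVariant
from .metrics import ShadedRegionSpec, compute_features
from .types import CompositeImage, MultichannelImage

__all__ = [
    "OptimizationReport",
    "trim_and_restitch",
    "optimize_multichannel",
    "profile_flatness",
]


@dataclass
class OptimizationReport:
    """Everything the optimizer decided, serializable to JSON."""

    rankings: dict[str, QualityRanking]
    selected: dict[str, str]
    features: dict[str, dict[str, list[float]]]  # channel -> variant -> raw features
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, ranking in self.rankings.items():
            if self.selected.get(ch) != ranking.best:
                raise ValueError(
                    f"selected method for channel {ch!r} must be the top of its ranking"
                )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected": self.selected,
            "rankings": {
                ch: [[vid, score] for vid, score in r.entries]
                for ch, r in self.rankings.items()
            },
            "features": self.features,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OptimizationReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        rankings = {
            ch: QualityRanking(channel_id=ch, entries=[(v, s) for v, s in ent])
            for ch, ent in payload["rankings"].items()
        }
        return cls(
            rankings=rankings,
            selected=payload["selected"],
            features=payload["features"],
            config=payload.get("config", {}),
        )


def trim_and_restitch(
    tiles: np.ndarray, overlap_fraction: float, grid: tuple[int, int] | None = None
) -> CompositeImage:
    """Remove the acquisition overlap from tiles and abut them.

    ``tiles`` is ``(n_rows, n_cols, T, T)`` (or ``(n_tiles, T, T)`` with an
    explicit ``grid``), each tile still carrying ``overlap_fraction`` of
    its side shared with each neighbour.  Half the overlap is removed from
    each side (5% per side for a 10% overlap); when the total trim is an
    odd pixel count, the leading (top/left) side trims one pixel less than
    the trailing side.
    """
    tiles = np.asarray(tiles, dtype=float)
    if tiles.ndim == 3:
        if grid is None:
            raise ValueError("flat tile list needs an explicit grid")
        n_rows, n_cols = grid
        tiles = tiles.reshape(n_rows, n_cols, *tiles.shape[1:])
    if tiles.ndim != 4 or tiles.shape[2] != tiles.shape[3]:
        raise ValueError("tiles must be (n_rows, n_cols, T, T) with square tiles")
    n_rows, n_cols, T, _ = tiles.shape
    total = int(round(overlap_fraction * T))
    if total >= T:
        raise ValueError(f"overlap trim of {total}px exceeds the tile size {T}")
    lead = total // 2
    trail = total - lead
    trimmed = tiles[:, :, lead : T - trail, lead : T - trail]
    Tt = T - total
    pixels = trimmed.swapaxes(1, 2).reshape(n_rows * Tt, n_cols * Tt)
    return CompositeImage(pixels=pixels, tile_size=Tt, grid=(n_rows, n_cols))


def optimize_multichannel(
    raw: MultichannelImage,
    variants: Mapping[str, Sequence[CorrectionVariant]],
    model: LDAModel,
    region: ShadedRegionSpec | None = None,
    binning: int = 1,
    method_priority: Sequence[str] = (),
) -> tuple[MultichannelImage, OptimizationReport]:
    """Score, rank and select the best correction of every channel.

    The raw channel enters each ranking as the ``raw`` variant if not
    supplied explicitly.  Features are computed with the configured shaded
    region and binning, maximum-normalized with the model's training
    maxima, scored, and the argmax variant per channel is merged into the
    output image.
    """
    out_channels: dict[str, CompositeImage] = {}
    rankings: dict[str, QualityRanking] = {}
    selected: dict[str, str] = {}
    feature_log: dict[str, dict[str, list[float]]] = {}

    for channel_id, channel_raw in raw.channels.items():
        channel_variants = list(variants.get(channel_id, ()))
        if not channel_variants and channel_id not in variants:
            raise ValueError(f"channel {channel_id!r} has no variants")
        ids = [v.method_id for v in channel_variants]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate variant ids for channel {channel_id!r}")
        if "raw" not in ids:
            channel_variants.insert(
                0, CorrectionVariant(method_id="raw", channel_id=channel_id,
                                     image=channel_raw)
            )
        images = {v.method_id: v.image for v in channel_variants}
        feats = {
            vid: compute_features(img, region=region, binning=binning).as_array()
            for vid, img in images.items()
        }
        ranking = rank_variants(
            model, feats, channel_id=channel_id, method_priority=method_priority
        )
        best = ranking.best
        out_channels[channel_id] = images[best]
        rankings[channel_id] = ranking
        selected[channel_id] = best
        feature_log[channel_id] = {vid: f.tolist() for vid, f in feats.items()}

    report = OptimizationReport(
        rankings=rankings,
        selected=selected,
        features=feature_log,
        config={
            "binning": binning,
            "region": None if region is None else vars(region),
            "method_priority": list(method_priority),
            "feature_names": list(model.feature_names),
        },
    )
    return MultichannelImage(channels=out_channels), report


def profile_flatness(
    image: MultichannelImage | CompositeImage,
    axis: int = 0,
    normalization: str = "max",
) -> np.ndarray:
    """Maximum-normalized 1D intensity profile of the grayscale sum.

    Summing the channel-sum image along ``axis`` (0 sums over rows and
    profiles along x) exposes the periodic dips at tile borders that
    residual vignetting leaves behind; a flat profile means the mosaic is
    gone.
    """
    if isinstance(image, MultichannelImage):
        gray = image.grayscale_sum()
    else:
        gray = image.pixels
    profile = gray.sum(axis=axis)
    if normalization == "max":
        peak = profile.max()
        if peak > 0:
            profile = profile / peak
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return profile
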