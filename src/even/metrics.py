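"""No-reference quality metrics for uneven illumination in tiled images.

Two metrics quantify the two visible symptoms of uneven illumination in a
stitched composite image:

* the **edge energy ratio** ``E_edge`` — the fraction of the tile-sum
  image's energy lying in a designated shaded region (tile borders for
  radial vignetting, one side for lateral shading).  Flat illumination
  yields a high ratio; vignetting drains energy from the borders and
  lowers it.
* the **positive prominence** ``P_+`` — the summed topographic prominence
  of the periodic peaks that the tile grid imprints on the sum-normalized
  power spectrum, at spatial frequencies ``±k·N/T`` (k = 1..T/2).  A clean
  image has no such peaks; a strong mosaic artifact produces tall ones.

Both metrics are invariant under positive rescaling of the image, so they
can be compared across acquisitions with different dynamic ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import peak_prominences
from skimage.measure import block_reduce

from .types import CompositeImage

__all__ = [
    "ShadedRegionSpec",
    "QualityFeatures",
    "rescale_unit",
    "percentile_normalize",
    "split_tiles",
    "tile_sum",
    "default_radial_threshold",
    "edge_energy_ratio",
    "power_spectrum",
    "mosaic_peak_frequencies",
    "harmonic_profile_indices",
    "positive_prominence",
    "negative_prominence",
    "magnitude_prominence",
    "compute_features",
    "FEATURE_NAMES",
]

#: Default feature vector, in column order.
FEATURE_NAMES = ("e_edge", "p_plus")


@dataclass(frozen=True)
class ShadedRegionSpec:
    """Definition of the shaded region used by the edge energy ratio.

    ``radial`` mode selects pixels farther than ``k_rad`` from the tile
    center (vignetting); ``lateral`` mode selects pixels whose x coordinate
    exceeds ``k_v`` (one-sided shading).  Thresholds are in pixels of the
    tile the ratio is evaluated on.
    """

    mode: Literal["radial", "lateral"] = "radial"
    k_rad: float | None = None
    k_v: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "radial":
            if self.k_rad is None or self.k_rad <= 0:
                raise ValueError("radial mode requires k_rad > 0")
        elif self.mode == "lateral":
            if self.k_v is None or self.k_v <= 0:
                raise ValueError("lateral mode requires k_v > 0")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def validate_for_tile(self, tile_size: int) -> None:
        if self.mode == "radial":
            if not self.k_rad < tile_size / np.sqrt(2):
                raise ValueError(
                    f"k_rad={self.k_rad} leaves an empty shaded region for "
                    f"tile size {tile_size} (need k_rad < T/sqrt(2))"
                )
        else:
            if not self.k_v < tile_size:
                raise ValueError(f"k_v={self.k_v} must be < tile size {tile_size}")

    def scaled(self, factor: float) -> "ShadedRegionSpec":
        """Rescale the pixel threshold (used when the image is binned)."""
        if self.mode == "radial":
            return ShadedRegionSpec(mode="radial", k_rad=self.k_rad * factor)
        return ShadedRegionSpec(mode="lateral", k_v=self.k_v * factor)


@dataclass(frozen=True)
class QualityFeatures:
    """Per-image feature vector with the settings it was computed under."""

    e_edge: float
    p_plus: float
    tile_size: int
    region_spec: ShadedRegionSpec
    binning: int = 1

    def as_array(self) -> np.ndarray:
        return np.array([self.e_edge, self.p_plus], dtype=float)


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Affinely map an image to [0, 1] (min -> 0, max -> 1).

    A constant image maps to all zeros by convention, which keeps every
    downstream ratio well defined without special-casing flat inputs.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def percentile_normalize(image: np.ndarray, p_lo: float, p_hi: float) -> np.ndarray:
    """Clip to the [p_lo, p_hi] percentile window, then map to [0, 1].

    Percentile normalization between 0 and 99 is the standard preprocessing
    for point-scanned acquisitions with a few saturated pixels.
    """
    if not 0 <= p_lo < p_hi <= 100:
        raise ValueError(f"need 0 <= p_lo < p_hi <= 100, got ({p_lo}, {p_hi})")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi == lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def split_tiles(composite: CompositeImage) -> np.ndarray:
    """Split a composite into its tiles, row-major.

    Returns an array of shape ``(n_rows * n_cols, T, T)``; concatenating the
    tiles back in row-major order reproduces the composite bit-exactly.
    """
    T = composite.tile_size
    n, m = composite.pixels.shape
    if n % T:
        raise ValueError(f"image height {n} is not divisible by tile size {T}")
    if m % T:
        raise ValueError(f"image width {m} is not divisible by tile size {T}")
    tiles = (
        composite.pixels.reshape(n // T, T, m // T, T)
        .swapaxes(1, 2)
        .reshape(-1, T, T)
    )
    return tiles


def tile_sum(composite: CompositeImage) -> np.ndarray:
    """Elementwise sum of all tiles: ``t_sum = sum_i t_i`` (shape T x T).

    Vignetting affects every tile identically, so summing the tiles
    averages out the sample structure and isolates the illumination decay.
    """
    return split_tiles(composite).sum(axis=0)


def default_radial_threshold(
    tile_size: float, rule: Literal["equal_area", "three_eighths"] = "three_eighths"
) -> float:
    """Default radial threshold k_rad for a tile of side T.

    ``equal_area`` sets ``k_rad = T / sqrt(2*pi)`` so the disk inside the
    threshold covers half the tile area; ``three_eighths`` uses the similar
    value ``3/8 * T`` (3/4 of the lateral tile size assumed flat).
    """
    if tile_size <= 0:
        raise ValueError("tile size must be positive")
    if rule == "equal_area":
        return tile_size / np.sqrt(2.0 * np.pi)
    if rule == "three_eighths":
        return 0.375 * tile_size
    raise ValueError(f"unknown rule {rule!r}")


def _tile_center_coords(tile_size: int) -> tuple[np.ndarray, np.ndarray]:
    # pixel-center convention: pixel (i, j) sits at (i + 0.5 - T/2, j + 0.5 - T/2)
    c = np.arange(tile_size) + 0.5 - tile_size / 2.0
    return c[:, None], c[None, :]


def edge_energy_ratio(composite: CompositeImage, region: ShadedRegionSpec) -> float:
    """Edge energy ratio E_edge = E_shaded / E_tot of the tile-sum image.

    Radial mode sums ``t_sum`` over pixels with ``sqrt(x^2 + y^2) > k_rad``
    (coordinates relative to the tile center, pixel-center convention;
    pixels at exactly ``k_rad`` belong to the central region).  Lateral mode
    sums over pixels with x coordinate ``> k_v``.  The result lies in
    [0, 1]; flat illumination keeps it high, vignetting lowers it.
    """
    T = composite.tile_size
    region.validate_for_tile(T)
    t_sum = tile_sum(composite)
    total = t_sum.sum()
    if total == 0:
        raise ValueError("zero total energy in tile sum")
    if region.mode == "radial":
        y, x = _tile_center_coords(T)
        shaded = np.hypot(x, y) > region.k_rad
    else:
        x = np.arange(T)[None, :] + 0.5
        shaded = np.broadcast_to(x > region.k_v, t_sum.shape)
    return float(t_sum[shaded].sum() / total)


def power_spectrum(image: np.ndarray) -> np.ndarray:
    """Sum-normalized power spectrum ``|F(I)|^2 / sum``, DC at the center.

    The output is fftshifted: for an ``N x M`` input the zero-frequency
    (DC) bin sits at index ``(N // 2, M // 2)``.  Entries sum to 1, so each
    bin is the fraction of image energy at that spatial frequency.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if not np.any(image):
        raise ValueError("all-zero image has no power spectrum")
    p = np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2
    return p / p.sum()


def mosaic_peak_frequencies(N: int, M: int, T: int) -> dict[str, np.ndarray]:
    """Signed spectral frequencies of the mosaic harmonics on each main axis.

    A grid of period ``T`` in an ``N x M`` image produces peaks at
    ``f_x = ±k·M/T`` and ``f_y = ±k·N/T`` for ``k = 1..T/2`` (``floor(T/2)``
    for odd T); DC is excluded.  For even image extent the Nyquist harmonic
    ``+L/2`` coincides with ``-L/2`` and is reported once, as ``-L/2``.

    Returns a dict with keys ``"fx"`` (frequencies along the column/x axis,
    in units of cycles per image width M) and ``"fy"`` (along the row/y
    axis, cycles per image height N).
    """
    if N % T:
        raise ValueError(f"image height {N} is not divisible by tile size {T}")
    if M % T:
        raise ValueError(f"image width {M} is not divisible by tile size {T}")
    out = {}
    for key, L in (("fy", N), ("fx", M)):
        ks = np.arange(1, T // 2 + 1)
        f = ks * (L // T)
        signed = set((-f).tolist()) | set(f.tolist())
        if L % 2 == 0 and L // 2 in signed:
            signed.discard(L // 2)  # Nyquist: +L/2 == -L/2, count once
        out[key] = np.array(sorted(signed), dtype=int)
    return out


def harmonic_profile_indices(L: int, T: int) -> np.ndarray:
    """Indices of the mosaic harmonics on an fftshifted axis profile.

    For a profile of length ``L`` (DC at ``L // 2``) from an image with tile
    period ``T``, returns the sorted in-range bin indices of the harmonics
    ``±k·L/T``, DC excluded, Nyquist (index 0 for even L) counted once.
    """
    dc = L // 2
    signed = mosaic_peak_frequencies(L, L, T)["fx"]
    idx = dc + signed
    idx = idx[(idx >= 0) & (idx < L)]
    return np.unique(idx)


def _axis_profiles(composite: CompositeImage) -> list[tuple[np.ndarray, np.ndarray]]:
    """The two main-axis profiles of the spectrum with their harmonic indices."""
    spec = power_spectrum(composite.pixels)
    n, m = spec.shape
    T = composite.tile_size
    profiles = [
        (spec[n // 2, :], harmonic_profile_indices(m, T)),  # f_x axis (f_y = 0)
        (spec[:, m // 2], harmonic_profile_indices(n, T)),  # f_y axis (f_x = 0)
    ]
    return profiles


def _localize_peak(profile: np.ndarray, idx: int) -> int | None:
    """Snap a harmonic bin to the strict local maximum within ±1 bin.

    Apodization and sample structure can displace a spectral peak by one
    bin; if no strict local maximum is found at idx-1..idx+1, the harmonic
    contributes nothing.  Profile-edge bins follow the edge-base convention
    and contribute 0 as well.
    """
    lo = max(idx - 1, 0)
    hi = min(idx + 1, len(profile) - 1)
    j = lo + int(np.argmax(profile[lo : hi + 1]))
    if j == 0 or j == len(profile) - 1:
        return None
    if profile[j] > profile[j - 1] and profile[j] > profile[j + 1]:
        return j
    return None


def _prominence_sum(composite: CompositeImage, transform) -> float:
    if min(composite.grid) < 2:
        raise ValueError(
            "the mosaic-peak metric needs a basic grid of tiles; use a "
            "composite with at least 2x2 tiles"
        )
    total = 0.0
    for profile, indices in _axis_profiles(composite):
        profile = transform(profile)
        peaks = sorted({j for i in indices if (j := _localize_peak(profile, int(i))) is not None})
        if peaks:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prom = peak_prominences(profile, peaks)[0]
            total += float(prom.sum())
    return total


def positive_prominence(composite: CompositeImage) -> float:
    """Summed prominence P_+ of the mosaic peaks in the power spectrum.

    Both main-axis profiles of the sum-normalized spectrum are scanned at
    the harmonic bins (DC excluded) and the topographic prominences of the
    strict local maxima found there are summed.  The value is the fraction
    of image energy standing out at mosaic frequencies: ~0 for a clean
    image, growing with artifact strength.
    """
    return _prominence_sum(composite, lambda p: p)


def negative_prominence(composite: CompositeImage) -> float:
    """Summed prominence of mosaic-frequency dips (exploratory variant).

    Computed like :func:`positive_prominence` on the negated profiles.
    Provided for exploration only; not part of the default feature vector
    and not validated.
    """
    return _prominence_sum(composite, lambda p: -p)


def magnitude_prominence(composite: CompositeImage) -> float:
    """P_+ computed on the spectral magnitude instead of the power.

    Exploratory variant; not part of the default feature vector and not
    validated.
    """
    return _prominence_sum(composite, np.sqrt)


def _bin_composite(composite: CompositeImage, binning: int) -> CompositeImage:
    if binning == 1:
        return composite
    T = composite.tile_size
    if T % binning:
        raise ValueError(f"binning {binning} does not divide tile size {T}")
    binned = block_reduce(composite.pixels, (binning, binning), np.mean)
    return CompositeImage(
        pixels=binned,
        tile_size=T // binning,
        grid=composite.grid,
        overlap_fraction=composite.overlap_fraction,
    )


def compute_features(
    composite: CompositeImage,
    region: ShadedRegionSpec | None = None,
    binning: int = 1,
) -> QualityFeatures:
    """Rescale, optionally bin, and compute the (E_edge, P_+) feature pair.

    The image is min-max rescaled to [0, 1], mean-pooled by ``binning`` in
    both directions (tile size and region thresholds scaled accordingly),
    and the two metrics are evaluated.  ``region`` defaults to the radial
    threshold at 3/8 of the (unbinned) tile size.
    """
    if binning < 1:
        raise ValueError("binning must be >= 1")
    if region is None:
        region = ShadedRegionSpec(
            mode="radial",
            k_rad=default_radial_threshold(composite.tile_size, "three_eighths"),
        )
    work = composite.with_pixels(rescale_unit(composite.pixels))
    work = _bin_composite(work, binning)
    scaled_region = region.scaled(1.0 / binning) if binning > 1 else region
    e = edge_energy_ratio(work, scaled_region)
    p = positive_prominence(work)
    return QualityFeatures(
        e_edge=e,
        p_plus=p,
        tile_size=composite.tile_size,
        region_spec=region,
        binning=binning,
    )
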