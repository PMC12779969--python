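"""Synthetic phantoms and the uneven-illumination degradation model.

A vignetted field of view is modelled as ``t = t0 * M + n`` where ``t0`` is
the ideal tile, ``M`` a multiplicative 2D Gaussian illumination mask
(maximum-normalized to 1, widths ``sigma_x, sigma_y`` and peak offsets
``x0, y0`` expressed as fractions of the tile side) and ``n`` a low level
of mixed Poisson-Gaussian noise.  A composite acquires the mosaic artifact
by applying the *same* mask to every tile.

Five artifact levels span mask widths from 1.2 (barely visible vignetting)
down to 0.4 tile sides (strong falloff), with peak offsets drawn uniformly
from [0, 0.2] tile sides per image.  These defaults define the study
conditions every downstream test and benchmark runs under.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .metrics import compute_features
from .types import CompositeImage

__all__ = [
    "MaskSpec",
    "NoiseSpec",
    "SimulationSpec",
    "gaussian_mask",
    "degrade_tile",
    "make_mosaic",
    "simulate_levels",
    "level_sigma_schedule",
    "synth_phantom",
    "build_training_set",
]

#: Table of study conditions: mask-width interval (fractions of tile side)
#: spanned linearly by the artifact levels, strongest last.
SIGMA_INTERVAL = (0.4, 1.2)
#: Peak-offset magnitudes are drawn uniformly from this interval.
OFFSET_INTERVAL = (0.0, 0.2)


@dataclass(frozen=True)
class MaskSpec:
    """Parameters of the Gaussian illumination mask.

    Widths and offsets are fractions of the tile side; offsets may carry a
    sign (the drawn magnitudes lie in [0, 0.2] with random sign).
    """

    sigma_x: float
    sigma_y: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("mask widths sigma_x, sigma_y must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Mixed Poisson-Gaussian noise model.

    ``poisson_scale`` is the photon budget at unit intensity (the masked
    signal is Poisson-resampled at that scale); ``gaussian_sigma`` is the
    std of the additive read-noise term, in intensity units.  Defaults are
    a low noise level: visually minor, SNR well above the artifact
    contrast.
    """

    gaussian_sigma: float = 0.01
    poisson_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be > 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for a multi-level degradation series."""

    n_levels: int = 5
    tile_size: int = 64
    grid: tuple[int, int] = (8, 8)
    noise: NoiseSpec | None = field(default_factory=NoiseSpec)
    sigma_schedule: tuple[tuple[float, float], ...] | None = None
    offset_interval: tuple[float, float] = OFFSET_INTERVAL

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 artifact levels")

    def sigmas(self) -> tuple[tuple[float, float], ...]:
        if self.sigma_schedule is not None:
            return self.sigma_schedule
        return level_sigma_schedule(self.n_levels)


def level_sigma_schedule(n_levels: int = 5) -> tuple[tuple[float, float], ...]:
    """Linear mask-width schedule, weakest (sigma = 1.2) to strongest (0.4).

    Level 1 has the widest mask (nearly flat illumination); the extension
    decreases by a constant step so that the last level reaches 0.4 tile
    sides.  For 5 levels this is (1.2, 1.0, 0.8, 0.6, 0.4).
    """
    lo, hi = SIGMA_INTERVAL
    s = np.linspace(hi, lo, n_levels)
    return tuple((float(v), float(v)) for v in s)


def gaussian_mask(tile_size: int, spec: MaskSpec) -> np.ndarray:
    """A T x T illumination mask, maximum-normalized to 1.

    ``M(x, y) = exp(-( (x - x0*T)^2 / (2*(sigma_x*T)^2)
                     + (y - y0*T)^2 / (2*(sigma_y*T)^2) ))``
    with (x, y) relative to the tile center (pixel-center convention),
    divided by its maximum so the brightest pixel is exactly 1.
    """
    if tile_size < 2:
        raise ValueError("tile size must be >= 2")
    T = tile_size
    c = np.arange(T) + 0.5 - T / 2.0
    y = c[:, None]
    x = c[None, :]
    m = np.exp(
        -(
            (x - spec.x0 * T) ** 2 / (2.0 * (spec.sigma_x * T) ** 2)
            + (y - spec.y0 * T) ** 2 / (2.0 * (spec.sigma_y * T) ** 2)
        )
    )
    return m / m.max()


def _apply_noise(signal: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    photons = rng.poisson(np.clip(signal, 0, None) * noise.poisson_scale)
    out = photons / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, size=signal.shape)
    return np.clip(out, 0.0, None)


def degrade_tile(
    t0: np.ndarray, mask: np.ndarray, noise: NoiseSpec | None = None
) -> np.ndarray:
    """Apply ``t = t0 * M + n`` to a single tile.

    With ``noise=None`` the degradation is exactly multiplicative.  With a
    noise spec, the masked signal is Poisson-resampled at the photon budget
    and Gaussian read noise is added; the result is clipped to >= 0.  The
    noise realization is fully determined by ``noise.seed``.
    """
    t0 = np.asarray(t0, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if t0.shape != mask.shape:
        raise ValueError(f"tile shape {t0.shape} does not match mask shape {mask.shape}")
    signal = t0 * mask
    if noise is None:
        return signal
    rng = np.random.default_rng(noise.seed)
    return _apply_noise(signal, noise, rng)


def make_mosaic(
    clean: CompositeImage, spec: MaskSpec, noise: NoiseSpec | None = None
) -> CompositeImage:
    """Degrade every tile of a composite with the same illumination mask.

    The identical per-tile mask is what turns vignetting into the periodic
    mosaic artifact of the stitched image.
    """
    T = clean.tile_size
    mask = gaussian_mask(T, spec)
    n_rows, n_cols = clean.grid
    full_mask = np.tile(mask, (n_rows, n_cols))
    signal = clean.pixels * full_mask
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        signal = _apply_noise(signal, noise, rng)
    return clean.with_pixels(signal)


def simulate_levels(
    clean: CompositeImage, sim: SimulationSpec
) -> list[tuple[CompositeImage, MaskSpec]]:
    """Generate the increasing-artifact-level series for one clean image.

    Level ``l`` (1-based) uses the l-th mask width of the schedule; peak
    offsets are drawn per level as uniform magnitudes from the offset
    interval with random sign.  Randomness derives entirely from
    ``sim.noise.seed``.  Returns ``[(degraded, mask_spec), ...]`` ordered
    from weakest to strongest artifact.
    """
    seed = sim.noise.seed if sim.noise is not None else 0
    rng = np.random.default_rng(seed)
    out = []
    for level, (sx, sy) in enumerate(sim.sigmas(), start=1):
        lo, hi = sim.offset_interval
        mag = rng.uniform(lo, hi, size=2)
        sign = rng.choice([-1.0, 1.0], size=2)
        spec = MaskSpec(sigma_x=sx, sigma_y=sy, x0=mag[0] * sign[0], y0=mag[1] * sign[1])
        noise = None
        if sim.noise is not None:
            # fresh, level-specific noise seed derived from the master seed
            noise = NoiseSpec(
                gaussian_sigma=sim.noise.gaussian_sigma,
                poisson_scale=sim.noise.poisson_scale,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        out.append((make_mosaic(clean, spec, noise), spec))
    return out


def synth_phantom(
    tile_size: int,
    grid: tuple[int, int],
    content: Literal["flat", "blobs", "fibers"] = "blobs",
    seed: int = 0,
    blob_density: float = 16.0,
    blob_sigma_frac: float = 0.25,
) -> CompositeImage:
    """A reproducible clean base image standing in for experimental data.

    ``flat`` is a constant 0.5 field; ``blobs`` scatters soft Gaussian
    blobs (cell-like intensity clusters, ``blob_density`` per tile, width
    ``blob_sigma_frac`` tile sides — a quarter tile by default, which keeps
    the phantom's spectral energy below the first mosaic harmonic);
    ``fibers`` draws smoothed oriented filaments (collagen-like structure).
    Output values lie in [0.1, 0.9] so the multiplicative degradation
    never hits an empty image.
    """
    if tile_size < 16:
        raise ValueError("tile size must be >= 16")
    n_rows, n_cols = grid
    shape = (n_rows * tile_size, n_cols * tile_size)
    if content == "flat":
        pixels = np.full(shape, 0.5)
    elif content == "blobs":
        rng = np.random.default_rng(seed)
        n_blobs = max(1, int(blob_density * n_rows * n_cols))
        impulses = np.zeros(shape)
        rr = rng.integers(0, shape[0], n_blobs)
        cc = rng.integers(0, shape[1], n_blobs)
        impulses[rr, cc] = rng.uniform(0.5, 1.0, n_blobs)
        pixels = gaussian_filter(impulses, sigma=blob_sigma_frac * tile_size)
        pixels = _to_unit_band(pixels)
    elif content == "fibers":
        rng = np.random.default_rng(seed)
        canvas = np.zeros(shape)
        n_fibers = 3 * n_rows * n_cols
        length = int(2.5 * tile_size)
        for _ in range(n_fibers):
            r = rng.uniform(0, shape[0])
            c = rng.uniform(0, shape[1])
            theta = rng.uniform(0, np.pi)
            dr, dc = np.sin(theta), np.cos(theta)
            steps = np.arange(length)
            rr = np.clip((r + steps * dr).astype(int), 0, shape[0] - 1)
            cc = np.clip((c + steps * dc).astype(int), 0, shape[1] - 1)
            canvas[rr, cc] += 1.0
        pixels = gaussian_filter(canvas, sigma=tile_size / 40.0)
        pixels = _to_unit_band(pixels)
    else:
        raise ValueError(f"unknown phantom content {content!r}")
    return CompositeImage(pixels=pixels, tile_size=tile_size, grid=grid)


def _to_unit_band(pixels: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    pmin, pmax = pixels.min(), pixels.max()
    if pmax == pmin:
        return np.full_like(pixels, (lo + hi) / 2.0)
    return lo + (hi - lo) * (pixels - pmin) / (pmax - pmin)


def build_training_set(
    n_good: int,
    n_bad: int,
    sim: SimulationSpec | None = None,
    seed: int = 0,
    content: str = "blobs",
    binning: int = 1,
    bad_level: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A labelled synthetic feature set for training the quality classifier.

    Each row comes from its own seeded phantom (one group per phantom, so
    groups never straddle labels).  Phantom content parameters (blob
    density and width) are drawn per sample, emulating the high structural
    variability of real training collections.  "Good" images are the clean
    phantom or its weakest (level-1) degradation — emulating well-corrected
    rather than ideal data.  "Bad" images emulate a homogeneous population
    of measurements with strong uneven illumination: all draw one strong
    artifact level (``bad_level``, default the second-strongest), their
    variability coming from peak offsets, noise and sample content rather
    than from a calibrated strength ladder.  Returns
    ``(features, labels, group_ids)`` with features in the column order of
    :data:`even.metrics.FEATURE_NAMES` and labels ``"good"`` / ``"bad"``.
    """
    if n_good < 5 or n_bad < 5:
        raise ValueError("need at least 5 samples per class")
    if sim is None:
        sim = SimulationSpec()
    if bad_level is None:
        bad_level = sim.n_levels - 1  # second-strongest mask
    if not 2 <= bad_level <= sim.n_levels:
        raise ValueError(f"bad_level must be in [2, {sim.n_levels}]")
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for i in range(n_good + n_bad):
        good = i < n_good
        phantom = synth_phantom(
            sim.tile_size,
            sim.grid,
            content=content,
            seed=int(rng.integers(0, 2**31 - 1)),
            blob_density=float(rng.uniform(6.0, 28.0)),
            blob_sigma_frac=float(rng.uniform(0.15, 0.35)),
        )
        level_sim = SimulationSpec(
            n_levels=sim.n_levels,
            tile_size=sim.tile_size,
            grid=sim.grid,
            noise=NoiseSpec(
                gaussian_sigma=sim.noise.gaussian_sigma if sim.noise else 0.0,
                poisson_scale=sim.noise.poisson_scale if sim.noise else 1000.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if sim.noise is not None
            else None,
            sigma_schedule=sim.sigma_schedule,
            offset_interval=sim.offset_interval,
        )
        series = simulate_levels(phantom, level_sim)
        if good:
            # clean phantom or its weakest degradation
            image = phantom if rng.random() < 0.5 else series[0][0]
        else:
            image = series[bad_level - 1][0]
        feats = compute_features(image, binning=binning)
        rows.append(feats.as_array())
        labels.append("good" if good else "bad")
        groups.append(i)
    return np.array(rows), np.array(labels), np.array(groups)
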