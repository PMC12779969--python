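"""Fourier-domain suppression of mosaic peaks, and external-variant adapters.

The periodic tile grid of a vignetted composite produces a lattice of
sharp peaks in the frequency domain at ``(±k_y·N/T, ±k_x·M/T)``.  Notching
those coefficients out — replacing each small neighbourhood by an estimate
of the local spectral background — removes the periodic component of the
artifact while leaving the rest of the spectrum untouched.  This is a
reconstruction in the spirit of the frequency-domain flat-field methods in
the literature; the exact suppression scheme of prior tools is not
standardized, so interpolation from an annular neighbourhood median is the
default here, with an attenuation mode as an alternative.

Corrections produced by external tools (e.g. BaSiC or CIDRE runs) enter
the pipeline as :class:`CorrectionVariant` objects; they are validated
against the raw grid metadata, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .metrics import mosaic_peak_frequencies
from .types import CompositeImage

__all__ = ["CorrectionVariant", "fourier_correct", "register_external_variant"]


@dataclass
class CorrectionVariant:
    """One correction of one channel, tagged with its provenance."""

    method_id: str
    channel_id: str
    image: CompositeImage
    provenance: str = ""


def _harmonic_lattice(
    N: int, M: int, T: int, axes_only: bool = False
) -> list[tuple[int, int]]:
    """Unshifted-FFT index pairs of the 2D mosaic harmonic lattice, DC excluded."""
    freqs = mosaic_peak_frequencies(N, M, T)
    fy = np.concatenate(([0], freqs["fy"]))
    fx = np.concatenate(([0], freqs["fx"]))
    points = []
    for a in fy:
        for b in fx:
            if a == 0 and b == 0:
                continue
            if axes_only and a != 0 and b != 0:
                continue
            points.append((int(a) % N, int(b) % M))
    return sorted(set(points))


def fourier_correct(
    composite: CompositeImage,
    notch_halfwidth: int = 1,
    mode: Literal["interpolate", "attenuate"] = "interpolate",
    axes_only: bool = False,
    background_factor: float = 2.0,
) -> CompositeImage:
    """Suppress the mosaic-peak lattice in the frequency domain.

    At every harmonic of the full 2D lattice ``(±k_y·N/T, ±k_x·M/T)``
    (DC excluded; only the two main axes if ``axes_only``), the complex
    DFT coefficients within ``notch_halfwidth`` bins (Chebyshev distance)
    are compared against the local spectral background, estimated from an
    annular ring two bins farther out.  Only coefficients whose magnitude
    exceeds ``background_factor`` times the ring's median magnitude — i.e.
    actual peaks standing above background — are touched: they are
    replaced by the ring's componentwise complex median (``interpolate``)
    or their magnitudes are reduced to the ring median with phases kept
    (``attenuate``).  An artifact-free image therefore passes through
    (essentially) unchanged.  The inverse transform's real part is clipped
    to >= 0; if the result exceeds 1 it is divided by its maximum.  The DC
    bin is never modified, preserving mean brightness.
    """
    n_rows, n_cols = composite.grid
    if n_rows < 2 or n_cols < 2:
        raise ValueError("fourier correction needs a grid of at least 2x2 tiles")
    if notch_halfwidth < 0:
        raise ValueError("notch_halfwidth must be >= 0")
    N, M = composite.pixels.shape
    T = composite.tile_size
    lattice = _harmonic_lattice(N, M, T, axes_only=axes_only)

    hw = notch_halfwidth
    offsets = [(dy, dx) for dy in range(-hw, hw + 1) for dx in range(-hw, hw + 1)]
    ring = [
        (dy, dx)
        for dy in range(-(hw + 2), hw + 3)
        for dx in range(-(hw + 2), hw + 3)
        if max(abs(dy), abs(dx)) > hw
    ]

    for py, px in lattice:
        if any((py + dy) % N == 0 and (px + dx) % M == 0 for dy, dx in offsets):
            raise ValueError(
                f"notch of halfwidth {hw} at harmonic ({py}, {px}) overlaps the "
                "DC bin; reduce notch_halfwidth"
            )

    if mode not in ("interpolate", "attenuate"):
        raise ValueError(f"unknown mode {mode!r}")
    F = np.fft.fft2(composite.pixels)
    Fc = F.copy()
    for py, px in lattice:
        ring_vals = F[
            [(py + dy) % N for dy, dx in ring], [(px + dx) % M for dy, dx in ring]
        ]
        box_rows = np.array([(py + dy) % N for dy, dx in offsets])
        box_cols = np.array([(px + dx) % M for dy, dx in offsets])
        bg_mag = np.median(np.abs(ring_vals))
        vals = Fc[box_rows, box_cols]
        peaked = np.abs(vals) > background_factor * bg_mag
        if not peaked.any():
            continue
        if mode == "interpolate":
            background = np.median(ring_vals.real) + 1j * np.median(ring_vals.imag)
            vals = np.where(peaked, background, vals)
        else:  # attenuate
            mag = np.abs(vals)
            factor = np.where(peaked, bg_mag / np.where(mag == 0, 1.0, mag), 1.0)
            vals = vals * factor
        Fc[box_rows, box_cols] = vals

    out = np.fft.ifft2(Fc).real
    out = np.clip(out, 0.0, None)
    peak = out.max()
    if peak > 1.0:
        out = out / peak
    return composite.with_pixels(out)


def register_external_variant(
    path: str | Path,
    method_id: str,
    channel_id: str,
    raw_grid_meta: CompositeImage,
    existing: Sequence[CorrectionVariant] = (),
    provenance: str = "",
) -> CorrectionVariant:
    """Load an externally produced correction and validate it for ranking.

    The image on disk must match the raw composite's dimensions; its grid
    metadata is inherited from ``raw_grid_meta``.  Registering a duplicate
    ``method_id`` for the same channel is an error.
    """
    from . import io  # late import: io depends on types only

    for v in existing:
        if v.method_id == method_id and v.channel_id == channel_id:
            raise ValueError(
                f"variant {method_id!r} already registered for channel {channel_id!r}"
            )
    image = io.read_composite(
        path,
        tile_size=raw_grid_meta.tile_size,
        grid=raw_grid_meta.grid,
        overlap_fraction=raw_grid_meta.overlap_fraction,
    )
    if image.shape != raw_grid_meta.shape:
        raise ValueError(
            f"variant {method_id!r} has shape {image.shape}, "
            f"expected {raw_grid_meta.shape}"
        )
    return CorrectionVariant(
        method_id=method_id, channel_id=channel_id, image=image, provenance=provenance
    )
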