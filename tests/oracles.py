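"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: definition-level DFTs, exhaustive
saddle searches, explicit loops.  None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np


def dft2_definition(img: np.ndarray) -> np.ndarray:
    """2D DFT straight from the definition, via explicit DFT matrices."""
    img = np.asarray(img, dtype=complex)
    N, M = img.shape
    u = np.arange(N)
    v = np.arange(M)
    Wn = np.exp(-2j * np.pi * np.outer(u, u) / N)
    Wm = np.exp(-2j * np.pi * np.outer(v, v) / M)
    return Wn @ img @ Wm.T


def prominence_exhaustive(y: np.ndarray, j: int) -> float:
    """Topographic prominence of ``y[j]`` by exhaustive saddle search.

    For each side, walk away from the peak until a strictly higher sample
    appears; the base on that side is the minimum encountered (the peak's
    own height if the walk is empty).  Prominence is the height above the
    higher of the two bases.  Edge samples get prominence 0 (edge-base
    convention).
    """
    h = float(y[j])
    if j == 0 or j == len(y) - 1:
        return 0.0
    bases = []
    for indices in (range(j - 1, -1, -1), range(j + 1, len(y))):
        low = h
        for i in indices:
            if y[i] > h:
                break
            low = min(low, float(y[i]))
        bases.append(low)
    return h - max(bases)


def p_plus_exhaustive(pixels: np.ndarray, tile_size: int) -> float:
    """Positive prominence recomputed from scratch with the exhaustive oracle.

    Reimplements the whole chain independently: sum-normalized shifted
    power spectrum, harmonic bins at multiples of L/T on each main axis
    (DC excluded, Nyquist once), +-1-bin localization to a strict local
    maximum, exhaustive-saddle prominence, summed over both axes.
    """
    p = np.abs(np.fft.fftshift(np.fft.fft2(pixels))) ** 2
    p = p / p.sum()
    n, m = p.shape
    total = 0.0
    for profile, L in ((p[n // 2, :], m), (p[:, m // 2], n)):
        spacing = L // tile_size
        dc = L // 2
        harmonics = set()
        for k in range(1, tile_size // 2 + 1):
            for idx in (dc - k * spacing, dc + k * spacing):
                if 0 <= idx < L and idx != dc:
                    harmonics.add(idx)
        peaks = set()
        for idx in sorted(harmonics):
            lo, hi = max(idx - 1, 0), min(idx + 1, L - 1)
            j = max(range(lo, hi + 1), key=lambda i: profile[i])
            if j in (0, L - 1):
                continue
            if profile[j] > profile[j - 1] and profile[j] > profile[j + 1]:
                peaks.add(j)
        for j in sorted(peaks):
            total += prominence_exhaustive(profile, j)
    return total


def tile_sum_loop(pixels: np.ndarray, tile_size: int) -> np.ndarray:
    """Tile sum by explicit python loops over the grid."""
    n, m = pixels.shape
    out = np.zeros((tile_size, tile_size))
    for r in range(n // tile_size):
        for c in range(m // tile_size):
            out += pixels[
                r * tile_size : (r + 1) * tile_size,
                c * tile_size : (c + 1) * tile_size,
            ]
    return out


def shaded_pixel_count(tile_size: int, k_rad: float) -> int:
    """Count of pixels strictly farther than k_rad from the tile center."""
    count = 0
    for i in range(tile_size):
        for j in range(tile_size):
            y = i + 0.5 - tile_size / 2.0
            x = j + 0.5 - tile_size / 2.0
            if np.sqrt(x * x + y * y) > k_rad:
                count += 1
    return count


def lda_closed_form(X: np.ndarray, y: np.ndarray) -> dict:
    """Pooled-covariance discriminant fitted by explicit closed-form algebra.

    Maximum-normalizes by column maxima, computes class means, the
    unbiased pooled covariance and coefficients ``Sigma^-1 mu_k`` with a
    plain matrix inverse.  Classes ordered (bad, good).
    """
    X = np.asarray(X, dtype=float)
    fmax = X.max(axis=0)
    Xn = X / fmax
    classes = ("bad", "good")
    means = np.array([Xn[y == c].mean(axis=0) for c in classes])
    n, F = Xn.shape
    pooled = np.zeros((F, F))
    for i, c in enumerate(classes):
        d = Xn[y == c] - means[i]
        pooled += d.T @ d
    pooled /= n - 2
    inv = np.linalg.inv(pooled)
    coef = np.array([inv @ means[i] for i in range(2)])
    priors = np.array([(y == c).mean() for c in classes])
    return {"means": means, "pooled": pooled, "coefficients": coef,
            "priors": priors, "feature_max": fmax}


def decision_score_by_hand(model_dict: dict, x: np.ndarray) -> float:
    """Evaluate the two decision functions term by term and difference them."""
    deltas = []
    for k in range(2):
        s = 0.0
        for f in range(len(x)):
            c = model_dict["coefficients"][k][f]
            mu = model_dict["means"][k][f]
            s += x[f] * c - 0.5 * mu * c
        s += np.log(model_dict["priors"][k])
        deltas.append(s)
    return deltas[1] - deltas[0]


def kendall_pair_count(order_a: list, order_b: list) -> float:
    """Kendall tau by exhaustive concordant/discordant pair counting."""
    pos_a = {v: i for i, v in enumerate(order_a)}
    pos_b = {v: i for i, v in enumerate(order_b)}
    items = list(order_a)
    conc = disc = 0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a = np.sign(pos_a[items[i]] - pos_a[items[j]])
            b = np.sign(pos_b[items[i]] - pos_b[items[j]])
            if a * b > 0:
                conc += 1
            else:
                disc += 1
    return (conc - disc) / (conc + disc)
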