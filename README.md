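# even

Evaluation and enhancement of flat-field corrections in tiled microscopy
images.

Large microscopy samples are imaged by raster-scanning many fields of view
(tiles) and stitching them into a composite. Non-uniform excitation and
detection make each tile brighter at its optical axis than at its borders
(*vignetting*); stitched together, the identical per-tile falloff becomes a
periodic grid pattern (the *mosaic effect*). Many flat-field correction
algorithms exist (BaSiC, CIDRE, Fourier-domain notch methods, …), but their
performance depends strongly on the channel content — so which correction is
best must be decided per image and per channel, ideally without a ground
truth. This package does that: it scores candidate corrections with
no-reference quality metrics, ranks them with a linear discriminant, and
assembles the best-scoring correction of every channel into one optimized
multichannel image. It is aimed at anyone post-processing tiled acquisitions:
multimodal nonlinear imaging (CARS/SHG/TPEF), widefield fluorescence mosaics,
slide scans.

## The metrics and the model

For a composite of N×M pixels built from T×T tiles:

* **Edge energy ratio** — vignetting affects every tile identically, so the
  elementwise tile sum t_sum = Σᵢ tᵢ isolates the illumination profile from
  the sample structure. The metric is the energy fraction in the shaded
  region,

      E_edge = Σ_{√(x²+y²) > k_rad} t_sum(x, y) / Σ t_sum(x, y),

  with coordinates relative to the tile center. The default radial threshold
  is k_rad = 3/8·T; k_rad = T/√(2π) splits the tile into two equal-area
  regions. A lateral variant (x > k_v) handles one-sided shading. Flat
  illumination ⇒ high E_edge.

* **Positive prominence** — the tile grid of period T produces peaks in the
  power spectrum P(f) = |F(I)|² at f_x = ±k·N/T, f_y = ±k·M/T (k = 1…T/2).
  P₊ is the summed topographic prominence of those peaks on the two main-axis
  profiles of the sum-normalized spectrum (DC excluded): the fraction of
  image energy standing out at mosaic frequencies. Clean image ⇒ P₊ ≈ 0.

* **Decision score** — the two metrics, maximum-normalized by the training
  set, feed a pooled-covariance linear discriminant with decision functions

      δ_k(x) = Σ_f (x_f c_{k,f} − ½ μ_{k,f} c_{k,f}) + log π_k,   c_k = Σ⁻¹μ_k.

  The scalar score δ_good(x) − δ_bad(x) is positive for images free of
  uneven illumination, and its magnitude ranks competing corrections.

The package also ships a seeded degradation simulator (t = t₀·M + n with a
maximum-normalized Gaussian mask M tiled over the grid, plus mixed
Poisson–Gaussian noise, five artifact levels of decreasing mask width
1.2→0.4 tile sides), a Fourier-domain corrector that notches the mosaic-peak
lattice, and the per-channel optimizer.

## Worked example

```python
from even import synth_phantom, compute_features, fourier_correct, default_model
from even.simulate import simulate_levels, SimulationSpec, NoiseSpec
from even.classify import score_raw

phantom = synth_phantom(64, (8, 8), content="blobs", seed=7)   # clean 512x512
series = simulate_levels(phantom, SimulationSpec(noise=NoiseSpec(seed=7)))
vignetted = series[3][0]                                       # level 4 of 5
corrected = fourier_correct(vignetted)

model = default_model()   # packaged model, trained on the synthetic generator
for name, image in [("clean", phantom), ("vignetted", vignetted),
                    ("fourier", corrected)]:
    f = compute_features(image)
    print(f"{name:10s} E_edge={f.e_edge:.4f}  P+={f.p_plus:.2e}  "
          f"score={score_raw(model, f.as_array()):+.1f}")
```

```
clean      E_edge=0.5540  P+=7.64e-04  score=+40.0
vignetted  E_edge=0.4906  P+=2.78e-02  score=-40.1
fourier    E_edge=0.5595  P+=4.54e-04  score=+45.3
```

Vignetting drains ~6 % of the tile-sum energy from the borders (E_edge
0.554 → 0.491) and concentrates ~3 % of the spectral energy into mosaic
peaks; the decision score flips from clearly good (+40) to clearly bad
(−40). The Fourier correction suppresses the peak lattice (P₊ drops 60×)
and restores a positive score. The same scoring drives the multichannel
optimizer (`even.optimize.optimize_multichannel`), which picks the
highest-scoring variant per channel and merges them.

A command-line interface covers the same workflow:

```bash
even simulate --content blobs --tile-size 64 --grid 8x8 --seed 7 --out-dir sims/
even metrics sims/level4.tif --tile-size 64 --binning 1 --out features.csv
even correct-fourier sims/level4.tif --tile-size 64 --out corrected.tif
even rank --model model.json --variants-dir variants/ --tile-size 64 --out ranking.json
even optimize --raw raw.tif --variants-dir variants/ --model model.json \
    --tile-size 64 --out optimized.tif --report report.json
```

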