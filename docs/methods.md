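# Methods

This note documents the models, conventions and design choices behind the
package, in the order of the processing pipeline.

## Degradation model and study conditions

A measured tile is modelled as t(x, y) = t₀(x, y)·M(x, y) + n(x, y): the
ideal tile t₀ multiplied by an illumination mask M and corrupted by additive
noise n. M is a 2D Gaussian, maximum-normalized to 1, parameterized by
widths (σ_x, σ_y) and peak offsets (x₀, y₀), all expressed as fractions of
the tile side T. A composite image acquires the mosaic artifact by applying
the *same* mask to every tile — the periodicity of the artifact is exactly
the tile period. The simulator reproduces these conditions:

* **Artifact levels.** Five levels with mask widths on a linear schedule
  from σ = 1.2 (level 1, barely visible vignetting) down to σ = 0.4
  (level 5, strong falloff), both axes equal by default. Peak-offset
  magnitudes are drawn uniformly from [0, 0.2] tile sides per image, with a
  random sign (only the magnitude interval is physically specified; the
  direction of the misalignment is arbitrary).
* **Noise.** Mixed Poisson–Gaussian: the masked signal is Poisson-resampled
  at a photon budget of 1000 photons per unit intensity, then Gaussian read
  noise of σ = 0.01 intensity units is added, and the result is clipped to
  ≥ 0. These values are a deliberately low noise level — visually minor,
  SNR well above the artifact contrast — chosen once as defaults because
  the noise magnitude of the original semi-synthetic experiments is not
  recoverable; absolute metric values therefore should not be compared
  against published curves, only trends.
* **Phantoms.** `synth_phantom` produces flat fields, soft Gaussian blobs
  (default width T/4, 16 per tile — cell-cluster-scale structure whose
  spectral energy stays below the first mosaic harmonic) and smoothed
  oriented filaments. Values live in [0.1, 0.9] so multiplicative
  degradation never yields an empty image. The default grid is 8×8 tiles of
  64 px: the harmonic comb needs a few tiles per axis to separate from the
  DC lobe, and small tiles keep every test and benchmark fast on one CPU.
* **Training surrogate.** `build_training_set` emulates a labelled
  collection: "good" rows are clean phantoms or their weakest (level-1)
  degradations — well-corrected rather than ideal images; "bad" rows are a
  *homogeneous* strong-artifact population, all drawn at one strong level
  (default the second-strongest, σ = 0.6), with variability coming from
  peak offsets, noise realizations and per-sample content jitter (blob
  density U[6, 28] per tile, width U[0.15, 0.35]·T). The homogeneity
  matters: a calibrated ladder of bad strengths would introduce a single
  dominant artifact axis into the within-class covariance and flip the sign
  of the whitened P₊ coefficient, which real heterogeneous collections do
  not show. Each row comes from its own phantom, which is also its group id
  for grouped cross-validation.

What the phantoms do **not** emulate: real point-spread functions, sample-
dependent background, stitching misregistration, non-Gaussian illumination
profiles, shading with limited periodicity (irregular stripes, temporal
drift). Passing tests therefore demonstrate correctness of the pipeline
mechanics and the qualitative metric behaviour, not quantitative agreement
with any experimental dataset.

## Quality metrics

Images are always min-max rescaled to [0, 1] before metric computation
(`rescale_unit`; a constant image maps to zeros by convention, avoiding a
divide by zero). Optional b×b mean binning precedes the metrics, with the
tile size and pixel thresholds scaled by 1/b; binning 4 matches common
practice for large acquisitions, binning 1 is the default for the small
synthetic images used here. Percentile normalization (clip to the
[p_lo, p_hi] percentile window, then map to [0, 1]) is available for
acquisitions with a few saturated pixels.

**Edge energy ratio.** Computed on the elementwise tile sum. Radial
coordinates use the pixel-center convention: pixel (i, j) sits at
(i + 0.5 − T/2, j + 0.5 − T/2), and pixels at distance exactly k_rad belong
to the central (non-shaded) region. The exact threshold is not critical for
ranking purposes; fixing the convention makes every value reproducible to
the last bit. Defaults: k_rad = 3/8·T (`three_eighths` rule; three quarters
of the lateral size assumed flat), with k_rad = T/√(2π) (`equal_area`)
available — by pixel counting, the disk inside that radius covers half the
tile area to better than 1 % for T ≥ 64. The lateral variant uses the
pixel-center x coordinate (j + 0.5 > k_v).

**Positive prominence.** The power spectrum |F(I)|² is sum-normalized (each
bin is an energy fraction) and fftshifted, DC at (N//2, M//2). The metric
reads the two main-axis profiles (f_y = 0 row and f_x = 0 column) at the
harmonic bins ±k·L/T, k = 1…⌊T/2⌋, DC excluded. For even L the Nyquist
harmonic +L/2 ≡ −L/2 is counted once (at profile index 0, where the
edge-base convention gives it zero prominence). At each harmonic the
strict local maximum within ±1 bin is located (tolerating one-bin peak
displacement); if none exists the harmonic contributes 0 — this keeps a
constant image at exactly 0. Prominence is the standard topographic
definition, evaluated by `scipy.signal.peak_prominences` on the
linear-scale profile, and is validated against an exhaustive saddle-search
oracle to 1e-12 relative. The metric needs at least a 2×2 tile grid;
with a single tile per axis the harmonic spacing collapses to one bin and
the measure is undefined. Negative-prominence and magnitude-prominence
variants are provided for exploration only and are not part of the default
feature vector or validated.

Both metrics are invariant under positive rescaling of the image, and the
power spectrum is invariant under spatial translation.

## Discriminant model

Features (E_edge, P₊) are maximum-normalized by the *training-set* column
maxima — also at prediction time, where values above 1 are allowed. The
classifier is a pooled-covariance linear discriminant fitted in closed
form: class means μ_k, unbiased pooled within-class covariance Σ
(denominator n − 2), coefficients c_k = Σ⁻¹μ_k, priors π_k empirical by
default (uniform on a balanced set) or explicitly uniform. If Σ is
near-singular (condition number > 1e12, possible with collinear features)
a ridge of 1e-8·trace(Σ)/F is added before inversion. The decision score
is δ_good(x) − δ_bad(x); exactly 0 resolves conservatively to "bad".
Internal consistency (Σ·c_k = μ_k) is asserted in tests, and predictions
are cross-checked against scikit-learn's LDA as an independent reference.

Cross-validation is grouped and class-stratified (5 folds by default,
scikit-learn `StratifiedGroupKFold`): all images derived from one sample
share a group and never straddle the train/test boundary; a group carrying
both labels is rejected. Sensitivity is the true rate for good images,
specificity the true rate for bad ones.

Rankings sort variants by decision score, with deterministic tie-breaking
by a configurable method-priority list and then lexically. Rank agreement
between two orderings uses Kendall's tau-b. The dataset-level quality
number for multichannel images is the per-channel population z-score of
the decision scores, summed over channels.

The packaged default model (`even/data/default_model.json`, regenerated by
`scripts/train_default_model.py`) is trained on the synthetic generator and
carries `metadata.training_data = "synthetic"`. It is a reasonable starting
point for artifact screening; quantitative work on experimental data should
retrain on a labelled subset of that data.

## Fourier correction

The corrector notches the full 2D harmonic lattice {(±k_y·N/T, ±k_x·M/T)}
(DC excluded; an axes-only mode exists). Around each lattice point, the
local spectral background is estimated as the median over an annular
Chebyshev ring two bins outside the notch. Only coefficients whose
magnitude exceeds `background_factor` (default 2.0) times the ring's median
magnitude are touched — actual peaks standing above background — so an
artifact-free image passes through essentially unchanged. `interpolate`
mode replaces them with the ring's componentwise complex median;
`attenuate` rescales their magnitude to the ring median, keeping phase.
Both operations are applied symmetrically in ±f, preserving conjugate
symmetry, and the DC bin is never modified, so mean brightness is
preserved up to the final clipping of residual negative ringing. The
output is clipped to ≥ 0 and divided by its maximum only if it exceeds 1
(a full min-max rescale would alter artifact-free images). The exact
suppression scheme of historical frequency-domain methods is not
standardized; this is a faithful-in-spirit reconstruction, with the notch
halfwidth (default 1 bin) and background factor exposed.

A notch overlapping DC (possible when the harmonic spacing, which equals
the tile count per axis, is ≤ the notch halfwidth + 1) is an error rather
than a silent brightness change.

## Optimizer

Overlapping acquisitions are trimmed by half the overlap per tile side
(5 % per side for a 10 % overlap) and abutted; when the total trim is an
odd pixel count, the leading (top/left) side trims one pixel less. The
optimizer scores every variant of every channel (the raw channel is always
entered as a variant), ranks them, selects the argmax and merges the
selections. Channels are scored strictly independently with a single
global feature normalization (the model's training maxima); no
cross-channel balance adjustment is applied. The report records rankings,
selections, features and the configuration, and round-trips through JSON.

## Known limitations

* **Flatness, not fidelity.** The metrics measure illumination flatness;
  they cannot distinguish a ground-truth clean image from a correction
  that flattens *beyond* the truth. Under exactly periodic synthetic
  degradation the notch corrector removes essentially the whole artifact
  and pins the tile sum near-uniform, so its output often scores at or
  slightly above the clean original (whose own content anisotropy and
  structural spectral baseline count against it). On synthetic benchmarks
  the corrected variant therefore ties with or beats the clean reference
  in a substantial fraction of channels. On experimental data corrections
  are imperfect and this degeneracy does not arise in the same way.
* Periodicity is assumed: shading with limited periodicity (irregular
  stripes, gradually varying illumination, temporal flashing) is outside
  the metrics' reach.
* The equal-mask assumption (one mask for all tiles) matches prospective
  acquisition pipelines; per-tile-varying illumination is not modelled.
* External corrections (BaSiC, CIDRE, …) are consumed as files and
  validated for shape only; the package does not reimplement them.
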