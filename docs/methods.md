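# Methods

## The detection model

Let `f ∈ ℝⁿ` be the spectral transmittance of a pixel on an n-band grid
(n = 14 by default) and `F` an n×q matrix of labeled training spectra from
c − 1 = 5 tissue classes: nucleus, cytoplasm, RBC, fiber, white area. The
basis is the eigendecomposition of the sample covariance

    C = (1/(q−1)) Σₖ (fₖ − f̄)(fₖ − f̄)ᵀ,

with eigenvectors `vᵢ` sorted by descending eigenvalue `λᵢ`. The fraction
of variance explained by m components is `Σᵢ≤ₘ λᵢ / Σᵢ λᵢ`. A pixel is
estimated from m components as `f̂ = f̄ + Σᵢ≤ₘ (vᵢᵀ(f − f̄)) vᵢ` and its
spectral error is `e = f − f̂`.

Because the five in-model classes span (to noise level) a 5-dimensional
affine subspace, m = 5 reconstructs them almost exactly, while the spectrum
of a class absent from `F` — the eosinophil — retains a residual whose sign
pattern reflects where its absorption departs from the modeled classes.
With `r` the band of the highest positive mean-residual peak and `s` the
band of the largest-magnitude negative peak, the per-pixel score
`d = e_r − e_s` is thresholded (`d ≥ T`) to segment the target class, and
the binary mask is cleaned by morphological closing and small-object
removal.

Choices made where the procedure itself is underdetermined:

- **Covariance normalization** is 1/(q−1). The eigenvectors and all
  variance *ratios* are identical under 1/q; nothing downstream depends on
  the distinction.
- **Eigenvector sign**: each column is flipped so its largest-magnitude
  entry is positive; signs are otherwise solver-dependent and this makes
  saved models reproducible. Equal eigenvalues are kept in solver order
  (stable sort); only the span matters to reconstructions.
- **"Peak"** means global extremum of the mean-error vector (that is all
  the two-band difference uses), with ties broken toward the lower band
  index. If the mean error has no strictly positive or no strictly
  negative entry the method is inapplicable and selection fails loudly.
- **Default m** is the number of in-model training classes (5),
  overridable per fit.
- **Threshold**: no fixed T is inherent to the method, so the default is
  Otsu's criterion on a 256-bin histogram of the d-map (unsupervised and
  reproducible), with a fixed-T override. A constant d-map yields an empty
  mask plus a warning rather than an error.
- **Morphology**: "dilation and erosion" is implemented as closing
  (dilate → erode) with a disk of radius 1, followed by removal of
  components below 20 px (sized for ~20× magnification); both are
  configurable. The cleanup is idempotent.
- **Overlay**: the painted boundary is the exact 8-connected outline of
  the mask (mask pixels adjacent to background) rather than a gradient
  edge detector — parameter-free and deterministic.
- The pipeline operates on **transmittance**, not absorbance, throughout;
  band indices are 0-based internally and reported 1-based.

## Band grid and reduction

The native acquisition is 55 samples at 5 nm spacing across 450–720 nm,
stored as degenerate (point-sample) bands. Averaging four contiguous bands
(the last group keeps its remaining three) yields the 14-band working grid
whose spans run 450–465 nm (band 1) through 710–720 nm (band 14); an
averaged band's range runs from its first to its last member wavelength.
Band averaging with group 1 is the identity, and it commutes with the
transmittance ratio whenever the glass reference is constant within each
group. The stated sensor sensitivity ranges are inconsistent across
sources (400–700 vs 400–720 nm); the implementation follows the tabulated
450–720 nm grid.

Transmittance is `i_s / i_g` with the glass signal floored at
`1e−6 · max(i_g)` (the ratio is undefined at zero glass signal). Values
slightly above 1 are kept — blank-area noise pushes pixels above unity and
clipping would bias the PCA mean — with an optional clip-to-[0, 1.05] flag.

## The phantom generator

`eoseg.synthetic` emulates the study conditions: transmittance follows
Beer–Lambert, `T(λ) = 10^(−[c_H a_H(λ) + c_E a_E(λ) + p(λ)])`, with

- **dye curves**: hematoxylin `a_H` = Gaussian peak at 600 nm (σ 45 nm,
  maximum on band 8 of the 14-band grid) plus a flat broadband floor of
  0.2 (hematoxylin absorbs far into the red — nuclei look dark blue, not
  cyan); eosin `a_E` = Gaussian peak at 525 nm (σ 30 nm). The curves are
  parameterizations, not digitized measurements.
- **class loadings** (c_H, c_E): nucleus (1.60, 0.15), cytoplasm
  (0.20, 0.40), RBC (0.08, 1.50), fiber (0.15, 0.90), white (0, 0),
  eosinophil (0.08, 1.50) — eosinophil and RBC are identical in their dye
  loadings and differ only through the perturbation below, so their
  broadband colors are nearly indistinguishable (< 5 % relative difference
  in the green and blue channels of the default RGB rendering, ~1 % in
  red).
- **eosinophil perturbation** `p(λ)`: an absorbance dipole with a positive
  lobe at 577.5 nm (weight 1.3) and a negative lobe at 637.5 nm (weight
  0.8), each a σ = 6 nm Gaussian, scaled by δ = 0.06 OD. Extra absorption
  at 577.5 nm depresses transmittance there (negative residual at band 7);
  the deficit at 637.5 nm raises it (positive residual at band 10). The
  narrow lobes keep the dipole nearly orthogonal to the smooth in-model
  endmembers — wide or symmetric lobes project substantially onto the
  5-class span and the leftover residual "rings" at neighboring bands,
  moving the negative extremum off band 7. The lobe asymmetry compensates
  for the smaller transmittance headroom under the eosin peak at 577.5 nm.
  δ is a free parameter of the generator: the true eosinophil–RBC spectral
  difference is not tabulated anywhere, only its hypothesized origin
  (differential hematoxylin uptake), which the dipole's placement around
  the hematoxylin peak encodes.
- **scene geometry**: a cytoplasm background with non-overlapping random
  ellipses per foreground class (area fractions: white 10 %, nucleus 8 %,
  fiber 8 %, RBC 6 %, eosinophil 4 %; semi-axes 3–8 px), placed with a
  1-px margin and bounded retries. Default image 256×256.
- **noise**: each pixel's spectrum is its class endmember times a
  per-pixel lognormal brightness factor (CV 2 %, mean 1 — staining and
  thickness variation) times per-band multiplicative Gaussian noise
  (SD 0.5 % — shot/readout noise after flat-fielding). One seeded
  generator drives everything; the seed and all settings are recorded in
  the scene's params.

The default training set is 600 spectra per in-model class (3000 total),
drawn from the same class models; eosinophil spectra for band selection
are drawn separately and never enter the training matrix.

**What the phantom does not model**: optical blur and the point-spread
function, chromatic aberration, scattering, stain colocalization gradients
within a cell, partial-volume mixing at region boundaries (truth masks are
pixel-exact), spatial noise correlation, and uneven illumination. Passing
the phantom benchmarks therefore demonstrates the internal consistency and
discriminative mechanism of the pipeline under its stated physics — not
clinical performance on real slides, where boundary mixing and
out-of-model structures would erode the precision/recall reported here.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at the
study sizes: 3000 training spectra, 256×256 phantoms over ten seeds for
the segmentation and baseline benchmarks (a 64×64 scene backs the cheap
unit tests). Oracle-agreement tests compare every numeric stage against
brute-force reimplementations (explicit covariance + dense symmetric
eigensolver, normal-equation projection, exhaustive argmax/argmin scans,
exhaustive between-class-variance maximization for Otsu, direct
structuring-element sweeps for morphology) at 1e−8, exact for binary
operations. Degenerate inputs are defined, not fatal: a constant residual
plane maps to mid-grey, a constant d-map gives an empty mask with a
warning, and an empty mask passes through cleanup and overlay unchanged.

The k-means baseline uses standard k-means++ initialization with ten
restarts and a fixed seed; its cluster matched to the eosinophil class is
the one with maximal ground-truth overlap, since cluster labels are
arbitrary. The RGB rendering integrates the cube through three Gaussian
broadband sensitivities (610/550/470 nm, σ 35 nm, row-normalized) — any
plausible broadband triple blurs the narrow two-band signature, which is
the point of the comparison.
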