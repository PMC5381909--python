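# Methods

## Measurement model

The forward model assumes ideal polarization optics.  A generator state
`g ∈ {H, V, +45°, R}` illuminates the sample with the unit-intensity Stokes
vector `s(g)`; the light leaves the sample as `S = M s(g)` with `M` the
per-pixel 4×4 Mueller matrix; an ideal analyzer (polarizer/quarter-wave
combination) in state `a ∈ {H, V, +45°, −45°, R, L}` transmits
`I(g, a) = ½ (S₀ + S₁a₁ + S₂a₂ + S₃a₃)`, the first Stokes component behind
the analyzer.  Note that an ideal depolarizer therefore transmits intensity
½ into every analyzer state — unpolarized unit-intensity light through a
perfect polarizer.

Reconstruction inverts this exactly.  Per generator state the output Stokes
vector is assembled from analyzer differences (`S₀ = I_H + I_V`,
`S₁ = I_H − I_V`, `S₂ = I_{+45} − I_{−45}`, `S₃ = I_R − I_L`) and the
Mueller columns follow from the four input states (`col0 = (S(H)+S(V))/2`,
`col1 = (S(H)−S(V))/2`, `col2 = S(+45) − col0`, `col3 = S(R) − col0`).
This is the canonical minimal-redundancy scheme for exactly these ten
states; with noiseless inputs the round trip is exact to machine precision
(the tests assert 1e−8).  Optional measurement noise is multiplicative
Gaussian per pixel (relative SD `noise_sd`), clipped at zero — a reasonable
stand-in for speckle/shot noise without modelling a specific camera.

The acquisition geometry (the instrument's off-backscatter angle) is not
modelled; maps are plain 2-D images, since the per-pixel algebra downstream
is geometry-independent.

## Polar decomposition

The Lu–Chipman factorization `M = M_Δ M_R M_D` is computed per pixel in the
canonical order: normalize by `m00`; build the diattenuator `M_D` from the
first row; form `M′ = M M_D⁻¹`; obtain the depolarizer block `m_Δ` from the
eigen-decomposition of `m′ m′ᵀ` (sign fixed by `det m′`); the retarder is
`M_R = M_Δ⁻¹ M′`.  Scalar maps: total depolarization
`Δ_T = 1 − |tr m_Δ|/3` (the 3×3-block form; the 4×4 variant coincides for
the diagonal depolarizers used throughout), retardance
`acos(tr M_R / 2 − 1)`, diattenuation `|D|`.

Numerical choices: the eigen-solve symmetrizes `m′ m′ᵀ` against roundoff and
clips tiny negative eigenvalues to zero; fully depolarizing pixels
(`m′ ≈ 0`) set `m_Δ = 0` and an identity retarder; pixels with `m00 ≤ 0` or
a singular diattenuator (`|D| ≥ 1`) are flagged invalid and removed from
the tissue mask rather than imputed — fabricated values would bias the
histogram the segmentation fits.  `Δ_T` is kept in [0, 1] internally and
only rendered as percent, so no double-scaling can occur.

All pixels are processed as one batched stack of 4×4 problems (numpy's
batched `solve`/`eigvalsh`), which keeps a 256×256 decomposition well under
a second.

## Local fuzzy thresholding

Five stages, each independently testable:

1. **Pre-processing** — Gaussian smoothing restricted to the tissue mask
   via normalized convolution (blur of value·mask divided by blur of mask,
   zero-padded), so background never bleeds into tissue.  Default
   `smooth_sigma` 1.5 px: small relative to the default 12 px rim width,
   enough to suppress single-pixel noise.
2. **Mixture fit** — an L-component 1-D Gaussian mixture fitted to the
   masked histogram by EM (L = 3: core, rim, healthy, identified by the
   rank of the component mean — the core depolarizes least).
   Initialization is deterministic: a multi-Otsu partition of the histogram
   seeds each component with its group's mass, mean and variance.  Otsu
   partitioning tracks the histogram's actual modes even when zone areas
   are very unequal — the realistic case of a small lesion in a large
   healthy sample, where equal-mass quantile seeding drops two components
   into the dominant healthy peak and EM stalls in a local optimum that
   merges core and rim.  Equal-mass quantiles remain as a fallback when
   thresholding fails.  The log-likelihood is asserted non-decreasing every
   iteration (the EM guarantee; variance flooring at 1e−12, the off-model
   escape for collapsing components, waives the assertion).  Convergence at
   `em_tol` 1e−7 or 300 iterations.  No random restarts, so the whole
   pipeline is deterministic given its input.
3. **Memberships** — the fuzzy membership of pixel r in class l is the
   posterior responsibility `μ_l(r) = w_l p_l(I(r)) / Σ_k w_k p_k(I(r))`,
   computed in log space; pixels whose densities all underflow are assigned
   crisply to the nearest-mean class.  This is the only membership
   construction derivable from the mixture model itself.
4. **Neighborhood aggregation** — each membership channel is replaced by
   its mean over the 3×3 window (background excluded from the average),
   then renormalized; two passes by default.  The smallest window that
   removes isolated misclassified pixels without erasing the thin rim;
   window and pass count are configurable.
5. **Labeling** — argmax over aggregated memberships; ties break toward
   the lower-mean class (lesion-conservative, and deterministic).

The global rigid baseline classifies each pixel by two fixed cut-offs
placed at the midpoints between the three sorted 50×50-ROI mean
depolarizations (the symmetric reading of "means determine cut-offs"); it
applies no smoothing and no spatial context, deliberately, to expose the
isolated-pixel artifact that motivates the fuzzy method.  ROI placement on
phantoms maximizes each zone's pixel count among windows with ≥ 90 % tissue
coverage, emulating manual placement near each zone's center; note a 50×50
window centered on a 12 px rim annulus unavoidably mixes in neighboring
zones, which is part of why rigid cut-offs overestimate the rim.

## Synthetic phantom

Geometry: an elliptical tissue sample (default 256×256 image, semi-axes
112×100 px) containing a lesion core (ellipse, semi-axes 42×34 px, offset
from the tissue center) whose outline is perturbed by a seeded low-order
harmonic series (orders 2–5, relative amplitude 0.1) so boundaries are
irregular but the topology is fixed; the rim is the Euclidean dilation of
the core by `rim_width` (default 12 px) restricted to tissue.  The lesion
occupies roughly a fifth of the sample, comparable to a ~1 cm² lesion in a
few-cm² imaged field.

Values: the map is (blurred zone-mean structure) + (white per-zone
Gaussian noise), clipped to [0, 1].  Blurring only the piecewise-constant
mean map (`transition_sigma`, default 1 px) creates the gradual inter-zone
transitions that defeat rigid thresholding, while leaving the noise white
and the interior per-zone statistics exactly at their configured values —
an ROI measurement on the final map reports the defaults 0.833 ± 0.035
(core), 0.877 ± 0.014 (rim), 0.915 ± 0.013 (healthy).  Blurring the drawn
noise together with the structure would shrink the per-pixel SD ~3.5-fold
at sigma 1 and silently change the stated study conditions.

The phantom deliberately matches the segmentation model's assumptions
(Gaussian zone histograms, compact zones): passing tests demonstrate the
pipeline's correctness and its behavior under the stated statistics, not
robustness to the things real tissue adds — spatially varying zone means,
non-Gaussian speckle, depth-weighted composite signals, staining/shrinkage
mismatch between the optical image and the histology ground truth.  DSC and
sensitivity on phantoms are accordingly *upper* ends of what matched
statistics allow, and the reported bounds are one-sided for that reason.

`make_mueller_phantom` lifts a Δ_T map to an ideal isotropic-depolarizer
Mueller field `diag(1, a, a, a)`, `a = 1 − Δ_T` (background: the zero
matrix, i.e. no light), which the decomposition inverts exactly; this links
the phantom to the full measurement chain for end-to-end tests.

## Evaluation

All confusion counts are one-vs-rest per class over tissue pixels only; the
image background is excluded from every cell (counting the large dark
background as true negatives would inflate specificity and accuracy
meaninglessly).  Dice uses the standard form `2tp/(2tp+fp+fn)`, defined as
1 when both sets are empty.  Accuracy is per target class, matching
per-region reporting.  Area agreement uses a least-squares slope through
the origin (ideal agreement = unit slope) and Bland–Altman bias ± 1.96 SD
limits; with constant differences the limits have zero width and no point
can fall outside.

`equalize_sizes` performs the only co-registration offered: rescaling one
map onto another's mask bounding box (nearest-neighbor for labels, bilinear
with mask normalization for scalars) — no rotation or elastic deformation,
mirroring the size-equalization approach the analysis is designed around.

## Problem sizes and determinism

Analysis drivers and acceptance use the default 256×256 phantom; a
five-phantom cohort (seeds 1–5) stands in for a five-sample study.  A full
phantom→segment→evaluate cycle takes ~1 s, the whole test suite well under
a minute.  Every stochastic step draws from `numpy.random.default_rng`
seeded explicitly; identical seed and config give bit-identical label maps
and byte-identical CSV outputs.

## Known limitations

- Ideal-optics model: no instrument calibration matrices, dark/flat-field
  correction, or eigenvalue filtering of experimental Mueller matrices.
- Only the Lu–Chipman product order `M_Δ M_R M_D` is implemented; no
  differential/logarithm decomposition.
- Δ_T uses the 3×3-block trace form; instruments reporting the 4×4 variant
  agree only for isotropic depolarizers.
- Retardance-based segmentation is out of scope; retardance is exposed as a
  by-product only.
- The rim width (px) of real lesions is unknown; the 12 px default is a
  free parameter, and the quality bounds are verified under the defaults
  only.
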