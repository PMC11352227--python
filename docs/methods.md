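# Methods

This note records the models, conventions and design choices behind
`perturbrad`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and containers

Volumes are `(x, y, z)` arrays with `z` the slice axis, 0-based indices,
and physical spacing/origin in mm taken from file headers (NIfTI, NRRD, or
DICOM series via SimpleITK). The default grid emulates a pelvic planning
CT: 0.98 × 0.98 mm pixels, 5 mm slices — strongly anisotropic, which is
why all physical-unit operations (LoG sigma, dose distances) work per-axis
in mm rather than assuming isotropy. Masks are binary, must share their
image's grid to 1e-3 mm (stricter tolerances proved brittle across format
round-trips), and are consumed as label volumes; RTSTRUCT polygon parsing
is out of scope. Dose maps must already be on the CT grid: the pipeline
never resamples dose, and the phantom generator sidesteps the question by
generating both modalities on one grid.

## Synthetic phantoms

A CT phantom is `tissue base + texture + speckle`:

* **Tissue base** — `n_tissue_levels` intensity plateaus laid out by
  quantiling a smooth random field (correlation length 4× the texture
  scale). By default the plateau span derives from the texture SD
  (`contrast`): adjacent plateaus sit 3 standard deviations apart, so each
  added compartment adds a distinguishable histogram mode. An explicit
  `tissue_range` overrides this.
* **Texture** — Gaussian-correlated noise (white noise smoothed per-axis
  to the `texture_scale` in mm, rescaled to SD `contrast` in HU).
* **Speckle** — 0.2% of voxels receive a ±300–500 HU offset, emulating
  partial-volume and streak artifacts. Speckle is part of the noise model
  (disabled when `contrast = 0`). It matters because fixed-bin-number
  discretization bins the *in-ROI range*: in near-homogeneous tissue, rare
  extreme voxels stretch that range and concentrate the bulk of voxels
  into few bins — this is precisely why homogeneous structures (bladder,
  target volume) show low first-order entropy and high uniformity on real
  CT, and without it a pure Gaussian texture has near-maximal histogram
  entropy at every contrast.

The dose phantom is `peak` Gy inside a target mask and
`peak · exp(−d/falloff)` at distance `d` mm outside (defaults 50 Gy,
10 mm), optionally plus smooth noise — flat dose in the target, sharp
fall-off with high in-ROI variance in adjacent organs, the qualitative
regimes that drive dosiomics repeatability. Five ellipsoidal/tubular ROI
stand-ins carry the pelvic labels (CTV, Bladder, Rectum, L/RFemoral),
pairwise disjoint, ≥ 200 voxels each.

Cohorts share the plateau layout (anatomy) but draw independent texture
realizations per subject, plus a subject intensity offset
`Normal(0, between_subject_sd)` (default 20 HU) applied to the CT and,
scaled by the tissue span, to the dose peak. That offset and the
realization-to-realization texture differences are the between-subject
variance the ICC must recover. All randomness fans out from a master seed
through `SeedSequence` spawn keys, so any subject or perturbation is
reproducible in isolation.

What the phantoms do *not* emulate: anatomical shape variation, scanner
noise spectra, beam physics, or dose-grid/CT-grid mismatches. Passing
tests therefore demonstrate the correctness and direction of the analysis
machinery, not clinical effect sizes.

## Perturbation model

Rigid moves sample tx, ty independently from {0, 0.4, 0.8} pixels and θ
from {−20, 0, +20} degrees (identity draws allowed), rotation about the
volume center in the axial plane only — sub-pixel z shifts are meaningless
at 5 mm slice thickness. Images resample with linear interpolation
(background −1000 HU for CT, 0 Gy for dose); masks resample linearly and
re-binarize at 0.5 (nearest-neighbour is not offered: at these small
transforms the 0.5-threshold behaves identically in expectation and keeps
contours smooth).

Contour randomization draws per-voxel x/y displacements from
Uniform(−1, 1) with dz ≡ 0 (contours are drawn slice by slice), divides by
the RMS vector magnitude over the field (RMS = 1 exactly), then smooths
each component with an isotropic 3D Gaussian of σ = 5 voxels. Smoothing a
normalized field collapses its RMS to ~0.03 voxel, so an amplitude knob is
required; here **amplitude is the RMS displacement in voxels**: at warp
time the smoothed field is rescaled so its RMS magnitude equals the
amplitude. The default of 3 voxels (~3 mm in-plane) was calibrated by
Monte-Carlo (`analysis/02_perturbation_calibration.py`): on a ~2000-voxel
ellipsoid it yields mean Dice ≈ 0.85 against the original contour,
matching reported inter-observer variability for pelvic organs. Masks are
warped backward through the field with linear interpolation and
re-thresholded at 0.5. One field is drawn per perturbation and applied to
every ROI; CT and dose of a subject consume the identical perturbation
set, and each (perturbation, ROI) has a single final mask shared by both
modalities. Composition is rigid-then-randomize per instance (the
alternative — separate perturbation arms — would halve the effective k).

## Filter bank and discretization

14 image types: original; LoG at σ = 1…5 mm computed as the sum of
per-axis second-derivative-of-Gaussian responses with σ in voxels =
σ_mm/spacing and each term divided by spacing² (physical Laplacian,
HU/mm²); and the 8 sub-bands of a single-level *undecimated* separable
coif1 decomposition (low/high-pass per axis), which keeps outputs on the
input grid so masks transfer without resampling. Boundary handling is
reflect everywhere. The sampled second-derivative kernels are corrected to
zero sum so constants map to exactly zero response — at σ_z = 0.2 voxel
(1 mm LoG on 5 mm slices) the uncorrected sampled kernel leaks DC.
Sub-voxel sigmas trigger a warning, not an error. No intensity
normalization and no isotropic resampling are applied before filtering.

Discretization is fixed-bin-number: 32 equal bins across the in-ROI
min–max of the *filtered, perturbed* image, recomputed per instance;
levels run 0–31, the maximum maps into the top bin, and a constant ROI is
all level 0.

## Features

93 features per image type, 1302 per vector. First-order entropy and
uniformity use the 32-bin discretized histogram (−Σp·log₂p, Σp²); the
other 16 first-order statistics use raw in-ROI intensities with
population (biased) moments, kurtosis not excess-corrected. Texture
matrices follow the IBSI-style conventions of the mainstream extractor:
GLCM and GLRLM use the 13 unique 3D directions at Chebyshev distance 1
with feature values averaged over directions; GLDM (dependence α = 0) and
NGTDM use the 26-neighborhood; GLSZM uses 26-connected zones. Gray levels
enter formulas as `level + 1` so the lowest bin carries weight. Matrices
are built on the mask bounding box for speed; out-of-mask neighbors never
contribute.

Degenerate inputs return documented limits instead of NaN (GLCM
correlation → 0 and MCC → 1 on a single-level matrix, NGTDM coarseness →
10⁶ on a flat image, skewness/kurtosis → 0 at zero variance); any
non-finite value that still arises is zeroed and flagged on the vector, so
a pathological ROI cannot poison the downstream ICC tables.

## Repeatability statistics

For each (feature, modality, ROI) stratum, the subjects × perturbations
matrix feeds a one-way random-effects ANOVA: MSR = k·Σ(x̄ᵢ−x̄)²/(n−1),
MSW = ΣΣ(xᵢⱼ−x̄ᵢ)²/(n(k−1)), ICC(1,1) = (MSR−MSW)/(MSR+(k−1)MSW). An
audit variant with denominator MSR+(k+1)MSW is selectable
(`denominator="k_plus_1"`) but non-standard. All-equal matrices (0/0) are
defined as ICC = 1 and flagged; negative ICCs are reported unclipped.
Missing entries are excluded pairwise: rows keep their available
perturbations, unbalanced sums of squares are used, and k is reported as
the mean per-subject count. The binarization threshold is ICC ≥ 0.9
(inclusive). Agreement between CT and dose is the four-way classification
both-high / both-low / CT-only / dose-only with counts and ratios per
image filter and per feature class.

## Image characteristics and correlations

Mean entropy, uniformity and variance are taken from the first-order
features of the *unperturbed* preprocessed images (averaging across
perturbations instead is available by filtering the feature table), then
averaged over subjects per (filter, ROI, modality) and joined with the
mean ICC of all features in that stratum. Pearson r with a two-sided
p-value is computed per modality across all (filter, ROI) points.

The heterogeneity-sweep study (`perturbrad.studies`) runs six cohorts
spanning bladder-like homogeneity (contrast 10 HU, one compartment, dose
fall-off 30 mm) to bone-like complexity (200 HU, six compartments,
fall-off 5 mm with 7 Gy smooth dose texture), 10 subjects × k = 10 by
default, on 48 × 48 × 8 grids with a 6-member filter bank (original,
LoG 1/5 mm, wavelet LLL/LLH/HHH) — sizes chosen so the full sweep runs on
a single CPU in minutes while leaving ~70 (filter, level) correlation
points per modality. The sweep disables speckle: speckle is a
perturbation-stable subject trait that inflates between-subject variance
(hence ICC) independently of texture, which would confound the
texture-complexity mechanism the study isolates. The expected finding —
computed, not assumed, by `analysis/04_characteristic_correlations.py`,
the acceptance script and the test suite — is a positive entropy–ICC and
negative uniformity–ICC correlation in both modalities: complex,
high-contrast images discretize into well-populated histograms whose
texture matrices are robust to interpolation and contour jitter, while
near-homogeneous images put most voxels into few bins and their features
reshuffle under perturbation.

## Numerical and testing notes

* Determinism: identical configs reproduce every CSV byte-identically;
  the pipeline's master seed fans out to subjects, perturbations and
  fields by fixed spawn keys.
* Oracles: the test suite checks the ICC against a brute-force two-loop
  ANOVA and against `pingouin`'s ICC(1,1); LoG against an FFT-convolution
  oracle with analytically sampled kernels; wavelet sub-bands against
  axis-by-axis direct convolution; every texture matrix against
  brute-force voxel/pair/run enumeration; GLCM scalar features against a
  loop-based formula transcription.
* Subject duplication (n → 2n with identical rows) leaves MSW unchanged
  and rescales MSR exactly by 2(n−1)/(2n−1); ICC is therefore *not*
  exactly invariant under duplication (it converges at O(1/n)), and the
  tests assert the exact rescaled value.
* The NGTDM neighborhood excludes voxels with no valid neighbor from the
  occupancy count; GLDM dependence is `1 + equal-level neighbors`, so
  every in-ROI voxel contributes.

## Known limitations

Phantoms are geometric, not anthropomorphic; dose fields are analytic,
not planned; the 24-feature GLCM roster pins one common convention (the
set listed in `perturbrad.texture.GLCM_NAMES`) where extractors differ at
the margins; ICC confidence intervals and two-way ICC variants are out of
scope; and desk-scale cohort sizes mean the study demonstrates signs and
mechanisms, not clinical magnitudes.
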