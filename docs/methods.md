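# Methods

`marginrad` implements a two-stage MR-radiomics analysis for detecting
residual cervical disease after conization, exercised end to end on
synthetic phantom cohorts. This note records the models, conventions and
numerical choices, and what the phantom experiments do and do not
establish.

## The analysis

**Stage 1 (model building).** Each case carries a T2-weighted volume, a
b=0/b=800 s/mm² DWI pair, and binary uterus / conization-cavity masks.
The ADC map is the two-point closed form of the mono-exponential decay
S(b) = S₀·exp(−b·ADC), i.e. ADC = ln(S₀/S(b))/b in mm²/s; voxels with a
non-positive signal are flagged invalid and excluded from all regions
downstream, and negative ADC values (noise pushing S(b) above S₀) are
permitted but reported. The analysis region is the band of uterine tissue
within 5 mm outward of the cavity surface, cleaned by an in-plane disk
erosion and intersected with the uterus; the band delineated on T2 is
applied unchanged to the ADC map. A fixed catalogue of 94 features per
sequence (16 first-order, 12 shape, 17 GLCM, 14 GLDM, 15 GLRLM, 15
GLSZM, 5 NGTDM) is extracted from each sequence over that volume of
interest (VOI). Features whose intra- or inter-observer ICC across
repeated delineations is ≤ 0.75 are discarded. On the training half of a
stratified 1:1 split, Boruta selects the all-relevant subset of the
surviving features. Two 500-tree random forests — one on all surviving
features, one on the Boruta subset — and the clinical positive-margin
flag are evaluated on the held-out half; AUCs are compared with the
paired DeLong test, and thresholded metrics use the Youden-optimal
threshold frozen on the training scores.

**Stage 2 (risk validation).** A second ("uterine preservation") cohort
is scored with the stage-1 model; cases at or above the frozen threshold
are high risk. Disease-free survival (time to confirmed residual or
recurrent disease, administratively censored at 36 months) is compared
between risk groups with the Kaplan–Meier estimator and the two-group
log-rank test.

One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence.spawn`, so the whole study is reproducible and
the stages are independently replayable.

## Preparation conventions

- **Normalization** is z-scoring over the uterus mask using the sample
  (ddof = 1) standard deviation, so in-mask values {1, 2, 3} map to
  {−1, 0, 1}; the transform is applied globally, making it idempotent and
  invariant to positive affine rescaling. It is applied to both sequences
  (configurable to `none`; ADC is quantitative, but z-scoring keeps the
  two sequences on one footing and removes scanner-level scale).
- **Discretization** is equal-width binning of the in-VOI intensity
  range into a fixed count of 32 gray levels (minimum → level 1, maximum
  → level N_g). A fixed bin count keeps texture-matrix sizes bounded and
  comparable across cases; the count is configurable.
- **No isotropic resampling** by default: texture distances are measured
  in voxels on the native anisotropic grid (an option exists to change
  the level count and band parameters per run).

## VOI construction

The band is defined as the set of voxels within `band_mm` (default 5) of
the cavity surface. The default digitization estimates that surface at
sub-voxel accuracy: the cavity indicator is upsampled 2× with linear
interpolation, thresholded at 0.5, and the Euclidean distance transform
of the result is thresholded at `band_mm`. On digitized spheres this
reproduces the analytic shell volume to within ±1.5%, whereas a plain
lattice dilation systematically under-reaches by about half a voxel per
surface (−5% on a 10→15 mm shell); the plain dilation remains available
(`mode="dilate"`, per-axis radius = max(1, round(band_mm/spacing))). The
band is intersected with the uterus, the cavity is removed, and the
result is eroded slice-by-slice with a discrete disk (x² + y² ≤ r²). The
erosion default is 3 pixels; the phantom study uses 1 pixel because its
1 mm in-plane grid is roughly three times coarser than a typical clinical
T2 matrix, and a 3-pixel erosion would consume the entire 5-voxel band.
Whether erosion precedes or follows the uterus intersection is a config
switch (default: erode the clipped band).

## Feature definitions

Standard radiomics definitions throughout. Specifics worth noting:

- First-order moments use the population (ddof = 0) convention; Kurtosis
  is the raw m₄/m₂² (not excess); Uniformity is computed on the
  discretized histogram; a constant sample returns 0 for Skewness and
  Kurtosis (flagged).
- Texture matrices use 26-connectivity: 13 unique directions at distance
  1 for GLCM (symmetrized, normalized per direction) and GLRLM, the full
  26-neighbourhood for GLDM (dependence tolerance α = 0), GLSZM
  (zone connectivity) and NGTDM. Per-direction features are averaged
  (features, not matrices, are aggregated). The GLDM matrix is indexed by
  dependence size j = (dependent neighbours) + 1, so an isolated voxel
  contributes j = 1.
- Degenerate denominators return documented sentinels rather than NaN:
  NGTDM Coarseness caps at 10⁶ on a flat region, Busyness/Strength return
  0, GLCM Correlation returns 1 for a zero-variance marginal, and a VOI
  with no co-occurring voxel pairs yields zero-filled GLCM features; all
  such cases are flagged in the feature vector.
- Shape: Volume is voxel count × voxel volume; SurfaceArea and mesh
  volume come from marching cubes on the zero-padded binary mask at the
  0.5 level — this surface carries a known constant staircase excess of
  roughly 7% on smooth objects, so Sphericity of digitized balls rises
  monotonically with radius toward a plateau slightly below 1. Diameters
  use the voxel-centre convention (largest pairwise distance between
  boundary-voxel centres, in 3D and within slice/column/row planes); axes
  are 4·√λ from the PCA eigenvalues of the physical voxel coordinates;
  VolumeRatio is voxel volume / mesh volume.

## ICC and Boruta

Intra-observer agreement uses ICC(3,1) (two-way mixed) and
inter-observer agreement ICC(2,1) (two-way random, absolute agreement,
single rater), both from the classical mean-square decomposition; a
feature is kept only if both exceed 0.75. Columns that are bitwise
identical have ICC 1 by definition; undefined ICCs (degenerate variance
with disagreeing raters) drop the feature.

Boruta follows the original algorithm: each iteration adds a shuffled
shadow copy of every feature, fits a random forest, and scores a hit for
each real feature whose importance exceeds the maximum shadow importance;
hits are tested against Binomial(n, ½) with Benjamini–Hochberg FDR
correction across the undecided features (two one-sided tests at
α = 0.01). Two deliberate implementation choices:

- **Importance is impurity (Gini) by default**, with permutation
  importance as an option. Impurity importance is what the reference
  Python implementation uses, and permutation importance over hundreds
  of real-plus-shadow columns costs two orders of magnitude more per
  iteration for no measurable change in the planted-recovery behaviour
  at these design sizes.
- **The shadow pool always contains shadows of every original feature**,
  not just the still-active ones. If shadows shrink with the active set,
  the max-shadow bar collapses late in a run and features that survived
  on spurious correlation get confirmed even on pure-noise data; with the
  full-width pool, null data yields zero confirmations.

Rejected features leave the forest; confirmed features keep competing
(all-relevant semantics — a duplicated informative feature is confirmed
twice); whatever is undecided after `n_iter` (default 100) stays
tentative. Boruta runs on the pooled T2WI+ADC feature set.

## Models and evaluation

Both classifiers are seeded random forests with 500 trees and √p
features per split. AUC is the Mann–Whitney (trapezoidal) statistic;
thresholded metrics (accuracy, sensitivity, specificity, PPV, NPV) are
computed at the training-Youden threshold and retain their confusion
counts. The positive-margin flag is evaluated as a two-valued score, so
its AUC equals its balanced accuracy. The DeLong test uses placement
values (structural components) with the tie-at-½ convention; when the
variance of the AUC difference is exactly zero the comparison is
deterministic and p is 1 (equal AUCs) or 0.

## The phantom generator

The generator provides the geometric and statistical structure the
analysis assumes, not MR realism. Geometry: the uterus is an ellipsoid
(default semi-axes 17 × 15 × 27 mm, jittered ±10% per case) on a
48 × 48 × 24 grid of 1 × 1 × 3 mm voxels; the conization cavity is a
cone-like frustum removed from its inferior pole, giving the containment
uterus ⊃ cavity ⊃ margin band. The DWI pair satisfies
b800 = b0·exp(−800·ADC) voxelwise before noise, so the ADC operation
inverts the construction exactly in the noiseless configuration.

**The planted lesion.** Residual cases carry a focal lesion: a blob of
the margin band around a random cavity-surface point (radius 4–10 mm)
with per-case conspicuity drawn from U(0.35, 1). The lesion is
diffusion-restricting but essentially T2-occult — as small high-grade
cervical lesions tend to be — lowering the local ADC toward the lesion
level (default 1.0×10⁻³ vs 1.4×10⁻³ mm²/s, attenuated ×0.8 and scaled by
conspicuity) and adding short-correlation (≈1 mm) ADC texture. Every
class contrast scales linearly with `texture_effect`; at 0 the two
classes are generated by an identical law (the null configuration), and
1.0 is the documented "strong" preset. This shape was chosen
deliberately: the all-relevant-selection advantage the study design
probes (Boruta model > all-features forest) only exists when the
informative features are few and moderately strong amid many irrelevant
ones. A whole-band, both-sequence lesion makes half the catalogue
informative and both models saturate; a compact ADC-focused lesion
reproduces that regime.

**Nuisance physiology.** Label-independent per-case variation — a
band-level intensity offset in T2 and ADC (post-surgical edema /
granulation), the smooth-versus-voxelwise noise composition, the texture
correlation length, and the geometry itself — survives per-case
z-scoring and makes whole feature families co-vary as correlated nuisance
blocks, as real radiomics features do. These blocks are what make the
all-features forest genuinely pay for its unselected inputs.

**Outcomes.** The positive-margin flag is a noisy correlate of the
residual label (sensitivity 0.65, specificity 0.70 — a realistic
operating point for margin status as a predictor of residual disease).
Follow-up times are exponential per class with administrative censoring
at 36 months; the residual hazard (0.043/month ≈ 79% event probability
by 36 months) is set so a 28-case preservation cohort at 18% prevalence
carries about 4 expected events, concentrated in true-residual cases,
and the nonresidual hazard is near zero (0.0005/month).

**Repeated delineation** is emulated by warping both masks with one
smooth random displacement field (≈3 mm correlation length) normalized
to an exact RMS amplitude: 0.4 mm for the intra-observer repeat and
0.75 mm for the second rater — plausible sub-voxel delineation
variability that keeps roughly 110–140 of the 188 features at the 0.75
ICC threshold. Topology is preserved by clipping the cavity to the
uterus and keeping largest connected components; zero jitter returns the
input unchanged.

**What the phantoms do not emulate:** MR physics (coil bias fields,
Rician noise), multi-observer bias structure, anatomy beyond the
ellipsoid/frustum idealization, competing risks or pregnancy. Passing
tests therefore demonstrate that the pipeline's operations are correct
and that the study's qualitative conclusions follow when their premises
hold — not that the method attains any particular accuracy on patient
images.

## Problem sizes and determinism

The phantom study runs at the original design sizes: 110 model-building
cases split 1:1, a 40-case repeatability subset, and a 28-case
preservation cohort. Monte-Carlo checks use 20 seeds for study-level
orderings, 5000 replicates for DeLong type-I calibration, and 2000
seeds for log-rank null uniformity; feature-definition checks sweep 100
random volumes (≤ 8×8×4, ≤ 8 gray levels) against brute-force
enumeration oracles at 10⁻⁹ relative tolerance. All randomness flows
from explicit integer seeds; repeated runs are bitwise identical.

## Known limitations

- The feature catalogue is fixed at the 94 ids per sequence listed in
  `catalogue_ids()`; filtered-image (wavelet/LoG) features and 2D modes
  are out of scope.
- Only the two-point ADC closed form is provided (no multi-b fitting,
  no bias-field correction).
- The binary-mask marching-cubes surface overestimates smooth areas by a
  known constant factor, which depresses Sphericity uniformly; rankings
  across cases are unaffected.
- The Boruta confirm/reject tests are repeated each iteration, which is
  anti-conservative in principle; the full-width shadow pool keeps the
  null behaviour clean in practice (zero confirmations on null data).
- Survival analysis is two-group KM/log-rank only; no Cox modeling or
  competing risks.
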