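# Methods

This note documents the models, conventions and numerical choices
behind `periradiomics`, in the order the pipeline runs them.

## Periluminal ring ROI

The analysis region is the shell of voxels immediately outside the
segmented coronary lumen.  "Two pixels" is interpreted on the native
voxel grid: a voxel belongs to the ring iff its 3-D Euclidean distance
to the nearest lumen voxel, measured in voxel units, lies in
(0, 2].  Distances come from an exact Euclidean distance transform, so
the ring around a single voxel contains exactly the 32 integer offsets
with squared norm ≤ 4.  The ring is clipped at the grid boundary and is
disjoint from the lumen by construction.

The ring is then *resegmented* to the −170…200 HU window: voxels
outside the window are removed from the ROI rather than having their
intensities clamped.  This is deliberate — the window exists to keep
contrast-opacified lumen (~400 HU) and dense calcium (>200 HU) out of
the periluminal statistics, which saturation would not achieve.  Both
bounds are inclusive.

When features are extracted under a resampled configuration, the ring
is rebuilt on the resampled mask (2 voxels of the *new* grid), so its
physical width varies with voxel size.  That variation is part of what
the stability screen measures.  Shape features are the exception: they
describe the segmentation itself and are computed once from the
original-geometry ring, so they are constant across configurations.

## Perturbation grid and resampling

21 imaging settings: the original grid, plus {0.50, 0.75, 1.0, 1.25,
1.5} mm isotropic targets × {trilinear, cubic B-spline, Welch windowed
sinc, nearest-neighbour} interpolation, in that fixed order.  The
output grid spans the same physical extent as the input (sizes rounded
up) with voxel centres aligned to the input origin.  Linear, B-spline
and nearest interpolation are delegated to SimpleITK with
nearest-neighbour extrapolation at the boundary.  The Welch windowed
sinc is implemented natively as a separable kernel of radius r = 3
samples per axis with window w(d) = 1 − (d/(r+1))², row-normalized to
unit DC gain so that constant fields are reproduced exactly (the ITK
kernel is not DC-normalized and fails that invariant by ~0.2%).
Masks are always resampled with nearest neighbour and stay binary.

## Feature bank

Four derived images: original; Laplacian of Gaussian at σ = 2 mm
(spacing-aware Gaussian smoothing followed by central-difference
Laplacian in physical units); gradient magnitude (spacing-aware central
differences); signed square root sign(v)·√|v|.  Families:

* **First order** (12): mean, variance, skewness, kurtosis, min, max,
  range, energy, RMS, mean absolute deviation, and entropy/uniformity
  on the discretized grey levels (entropy in bits).  Central moments use
  the population (1/N) convention; skewness and kurtosis of a constant
  or single-voxel ROI are defined as 0.
* **GLCM** (5): Contrast, Correlation, InverseVariance
  (Σ_{i≠j} p(i,j)/(i−j)²), Idm, JointEntropy.  Symmetric co-occurrence
  at distance 1 over the 13 unique 3-D directions, normalized per
  direction; features are averaged over directions that contain at
  least one co-occurring ROI pair, and are all 0 if no direction does.
  Correlation of a degenerate (single-level) direction is defined as 1.
* **NGTDM** (5): Coarseness, Contrast, Busyness, Complexity, Strength.
  s_i sums |i − mean of the valid 26-neighbourhood| over ROI voxels of
  level i; voxels with no ROI neighbour are excluded from N.
  Strength = Σ_{p_i,p_j>0} (p_i+p_j)(i−j)² / (ε + Σ s_i) with
  ε = 1e−12; Coarseness = 1/max(Σ p_i s_i, ε), capped at 1e12.
* **Shape** (4): voxel-count volume (mm³), face-counted surface area
  (mm²), sphericity π^{1/3}(6V)^{2/3}/A, and maximum 3-D diameter over
  voxel centres (computed on the convex hull of the surface voxels for
  large masks; full pairwise fallback for degenerate point sets).

Discretization is fixed-bin-width: level(v) = ⌊(v − anchor)/w⌋ + 1.
Original images anchor at −170 HU with w = 25 HU, making bins
comparable across subjects within the HU window (Ng = 15).  Derived
images are not in HU, so they anchor at the ROI minimum with per-filter
widths (LoG and gradient 25, square root 1.0) chosen to give a usable
number of grey levels on each value scale; all widths are configuration
values surfaced in the extraction manifest, not claims about any
external study's settings.

Feature names follow `<filter>_<family>_<Feature>`
(e.g. `squareroot_ngtdm_Strength`); shape features carry
`original_shape_`.  92 features per subject with the default filters.

## Stability screen

Δr of a feature = mean over subjects of (sample SD across the 21
configurations) / (|mean across configurations| + ε), ε = 1e−12.
Stable: Δr < 0.25; highly stable: Δr < 0.1.  The coefficient of
variation was chosen as the dispersion measure because a percentage
threshold implies a relative, unit-free quantity; the exact formula is
recorded in the report metadata so an alternative (e.g. relative range)
can be swapped behind the same interface.  Per-configuration stability
is the mean over subjects of |v_c − v_0|/(|v_0| + ε) against the
original setting, with the per-configuration stable fraction defined as
the share of features below 0.25.  All-zero features get Δr = 0 through
the ε guard and are flagged degenerate.  Stability flags are a pure
function of the stored Δr values and thresholds, so they survive
serialization round trips.

A Spearman rank-correlation helper (mid-ranks for ties; NaN for
constant inputs) supports feature-versus-calcium-score association
analyses.

## Feature reduction and pipeline variants

Pearson pruning walks features in descending-variance order (zero
variance dropped first) and keeps a feature iff |r| ≤ 0.9 against every
feature already kept — deterministic, idempotent, and configurable to a
stability-rank ordering, since which member of a correlated pair to
retain is a genuinely open choice.

LASSO-CV fits one-vs-rest L1-penalized logistic regressions per class
on per-fold standardized features, over a 50-point log-spaced,
data-scaled λ grid (from the smallest penalty that zeroes every
coefficient down three decades); λ minimizes mean cross-validated
deviance, and the support is the union of nonzero coefficients across
classes (a single fit for binary problems).  Fold assignment is
seeded.

Variants: (1) all features; (2) stable only; (3) Pearson+LASSO on all;
(4) stable → Pearson+LASSO; (5) variant 4 plus clinical covariates.
Clinical covariates join *after* selection and are not penalized: they
are few, pre-chosen and on their own scales, so shrinking them against
hundreds of radiomic features would conflate two different questions.

## Classification harness

Stratified outer 5-fold split; inside each outer training portion a
stratified 20% *inner test* set is held out and the model is fit on the
remaining 80%.  Reported "train"/"test" accuracies are fit-set and
pooled inner-test accuracies; the outer held-out fold is reported as
"validation".  This is a documented convention resolving genuinely
ambiguous wording about simultaneous validation and test sets — both
numbers are always reported.  Accuracy CIs are exact Clopper–Pearson
95% intervals on pooled counts.  AUCs are one-vs-rest trapezoidal;
micro pools the binary indicators, macro averages classes unweighted.
Leakage is asserted by index bookkeeping (fit, inner-test and
validation sets are pairwise disjoint within a fold).

The six-entry registry: RBF-SVM (C = 10, standardized), 5-NN
(standardized), one-hidden-layer MLP (64 units, standardized), Gaussian
naive Bayes, scikit-learn gradient boosting (150 trees, depth 3), and
LightGBM (leaf-wise growth, 150 trees, 15 leaves).  Hyperparameters
are fixed defaults — no search — because the comparison of interest is
between feature pipelines, not tuned learners.

## Shapley explanation

The value function is interventional: v(S) is the mean model output
over an explicit background set with the explained instance's values
imposed on the features in S; the explained scalar is the predicted
class's probability.  Exact mode enumerates all 2^M subsets (M ≤ 12)
with weights |S|!(M−|S|−1)!/M!, so efficiency
φ₀ + Σφ_j = f(x′) holds to < 1e−8, symmetric features get equal φ and
ignored features exactly 0.  Beyond 12 features a permutation-sampling
estimator (seeded, value-cached, unbiased) takes over.  Cohort
summaries rank features by mean |φ| and export per-subject signed
values for beeswarm-style plots.

## Synthetic phantoms: what they emulate, and what not

One vessel segment per phantom: a tube of lumen attenuation 400 HU
around a (by default straight, laterally jittered) centerline, a
periluminal fat sheath at −80 HU, soft-tissue background at 40 HU —
placing fat and soft tissue inside the −170…200 HU window and lumen
outside it, as the window intends.  Stenosis is a raised-cosine radial
indentation (severity = peak fractional diameter reduction, ≤ 0.9); the
space between the narrowed and the baseline lumen is filled with
fibrous-plaque-like tissue at 60 HU, so narrowing produces both a
geometric and an intensity signature in the ring.  Calcified plaques
are Gaussian blobs (σ = radius/2) with peaks in 130–1000 HU, composited
by maximum.  Acquisition noise is additive Gaussian (default SD 15 HU).
Ground truth is computed noise-free: Agatston score by the per-slice
technique below, stenosis percent from the continuous radius profile
that rasterizes the lumen (measuring diameters back off the voxelized
mask would add grid-dependent error that can flip a grade at boundary
severities).

Agatston scoring: per axial slice, 8-connected lesions of voxels
≥ 130 HU with in-plane area ≥ 1 mm² contribute area × weight, weight
1/2/3/4 by lesion peak HU (130–199/200–299/300–399/≥400); slice scores
are summed and scaled by slice thickness / 3 mm.  Lesions are never
merged across slices (the classic technique is per-slice).  Category
bins: [0,10] → 0, (10,100] → 1, (100,400) → 2, ≥400 → 3; a score of
exactly 400 is class 3, resolving the printed gap between "101–399"
and "above 400" in favour of the ≥ 400 reading.  Stenosis grades:
four-way <10 / 10–49 / 50–70 / >70%, three-way <10 / 10–49 / ≥50%.

The default study cohort is 120 phantoms on a 36×36×14 grid at
(0.5, 0.5, 3.0) mm — 40 per stenosis grade (severities U(0, 0.05),
U(0.15, 0.45), U(0.55, 0.85); lengths U(12, 18) mm), with calcific
burden drawn from four tiers targeting the four Agatston categories and
distributed 60/25/10/5% → 15/45/25/15% → 5/15/35/45% across the three
grades, so that burden rises with stenosis severity as it does in
clinical cohorts; segment labels (LMA, LCX, LAD, pRCA, mRCA) cycle
through the cohort.  Feature stability is screened on a separate
15-phantom lesion-free subcohort across all 21 settings, mirroring the
disease-free reference population such screens are run on; screening
the diseased cohort across the grid would multiply extraction cost
without changing what the screen estimates.  These sizes keep the full
study, including 435 ring extractions and six classifiers on two tasks,
in the low minutes on one CPU while leaving every class with enough
members for stratified 5-fold splits.

The generator does **not** emulate: photon/physics CT effects
(beam hardening, motion, partial-volume blur beyond rasterization),
multi-vessel tree topology, eccentric or non-circular lumina,
non-calcified plaque heterogeneity, or scanner-specific noise texture.
Passing tests therefore demonstrate that the pipeline's *mechanics* are
correct and that it recovers signals of the planted kind; they say
nothing about classification accuracy on real CCTA, where class overlap
is far larger.

A table-level cohort generator complements the image phantoms for
testing the screens directly: Gaussian features with planted per-class
mean shifts, equicorrelated blocks (Cholesky; duplicated columns at
ρ = 1), per-configuration multiplicative perturbation of a designated
unstable set (default SD 0.30), clinical covariates with mean-imputed
missingness, and seeded reproducibility.

## Degenerate inputs and numerical conventions

* ε = 1e−12 guards every relative quantity (CV, per-config deviation,
  NGTDM Strength/Coarseness).
* Empty ROI after resegmentation → the subject's feature vector is NaN
  and flagged; empty lumen → empty ring, not an error.
* GLCM with no co-occurring pairs → features 0 (logged); NGTDM with an
  empty ROI → error.
* All-zero stability features → Δr = 0, flagged degenerate.
* LASSO may legitimately select an empty support at strong penalties.
* All stage seeds derive from one root seed with fixed offsets
  (kept < 2³¹), so stages are independently reproducible and identical
  configurations re-run to byte-identical CSV outputs.

## Known limitations

* The feature bank is a representative, oracle-tested subset (~92
  features: 4 filters × 3 families + shape), not the thousands a full
  radiomics library emits; the analysis logic is feature-count
  agnostic.  GLRLM/GLSZM/GLDM families, wavelet filters and 2-D modes
  are out of scope.
* Discretization parameters and GLCM geometry are package defaults
  exposed in configuration, not values matched to any external study.
* The per-segment stenosis models train on small per-segment cohorts in
  the default study; the pooled model is the meaningful headline there.
* No survival modelling, external-cohort validation, or nnU-Net lumen
  segmentation: lumen masks are inputs.
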