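# Methods

`deltarad` models how a breast tumor changes during the first cycles of
neoadjuvant chemotherapy (NACT) as seen in longitudinal dynamic
contrast-enhanced MRI (DCE-MRI), and asks whether those changes predict the
eventual pathological response. Change is quantified at two levels:

- **voxel level** — a deformable registration aligns the early follow-up
  scan to the baseline scan; the Jacobian determinant of the resulting
  transformation measures local volume change (`< 1` shrinkage, `= 1`
  preservation, `> 1` expansion);
- **feature level** — radiomic features are extracted from the tumor ROI at
  both time points and summarized as the relative net change
  `delta_i = (f_i_baseline - f_i_followup) / f_i_baseline` (deltaRAD), so a
  positive value means the feature decreased under treatment.

Radiomic features from four image sources (baseline subtraction image,
follow-up subtraction image, Jacobian map, deltaRAD) feed support-vector
classifiers with recursive feature elimination; molecular subtype can be
appended to the fused feature set. Models are selected on a development arm
and evaluated once on a held-out testing arm.

## Response definition and cohort statistics

Pathological response uses the Miller-Payne (MP) grade of the surgical
specimen: grades 4–5 (> 90% tumor-cell loss; near-pCR/pCR) define
*responders*, grades 1–3 *nonresponders*. Cohort filtering applies
exclusion flags in a fixed order (missing imaging, missing MP outcome,
missing clinical data); a record with several flags counts under the first
applicable reason, and the report always balances.

Arm comparisons use one-way ANOVA for continuous covariates and, for
categorical covariates, the chi-square test — with Yates' continuity
correction on 2×2 tables — switching to Fisher's exact test whenever any
expected cell count is below 5. The 2×K Fisher test enumerates every table
consistent with the observed margins and sums the probabilities of tables
no more likely than the observed one (probability-mass two-sided rule, with
a 1e-7 relative tie tolerance). This is the rule that standard statistical
environments apply, and it reproduces their p-values exactly; the
enumeration is guarded by a table-count bound. Note that for R×C tables
larger than 2×2 the chi-square branch applies no continuity correction.

## Synthetic cohort generator

Patient imaging is simulated because the package must be exercisable end to
end without any data download. Each patient is a textured ellipsoidal
enhancing tumor (semi-axes 9–14 mm) in a 64³ volume at 1 mm isotropic
spacing. A DCE series is one precontrast frame plus four postcontrast
frames whose tumor enhancement follows a fixed profile peaking at the third
postcontrast frame, mimicking the wash-in/plateau behaviour of breast
lesions. Intratumoral heterogeneity is a correlated Gaussian random field
(3 mm length scale, SD 60 intensity units against a 150-unit
tumor–background contrast). Smooth multiplicative bias fields (±10%) and
Gaussian noise (SD 2) complete each frame.

The follow-up scan is the baseline warped through a known displacement
field: a per-axis affine contraction about the tumor centroid composed with
a small smooth residual field (0.5 mm amplitude), tapered to zero away from
the tumor. The warp is applied by inverting the forward map with a
fixed-point iteration and sampling with cubic splines, so the ground-truth
field is exact and texture is preserved. Treatment effects are planted with
class-dependent parameters:

| parameter | responders | nonresponders |
| --- | --- | --- |
| per-axis contraction (mean ± SD) | 0.75 ± 0.05 | 0.95 ± 0.05 |
| heterogeneity reduction (variance shrinkage toward the tumor mean) | 0.40 | 0.10 |

The responder fraction is 44/114 and the development-arm fraction 61/114,
matching the observed cohort composition; clinical covariates (age,
menopausal status, family history, molecular subtype with HR/HER2/Ki-67
receptor consistency, MP grade conditional on response class) are drawn
with the observed marginal proportions. All randomness flows from one
`numpy.random.SeedSequence`; there is no global random state.

What the generator does *not* emulate: pharmacokinetic (Tofts-type)
enhancement dynamics, scanner- and field-strength-specific contrast or
artifacts, non-mass-like or multifocal lesions, and anatomical background
(parenchyma, chest wall). Passing tests therefore demonstrate that the
pipeline recovers planted effects of realistic magnitude under controlled
imaging physics — not clinical performance on patient data.

## Preprocessing

**Bias correction** is a log-domain smooth-field estimator: a degree-3
polynomial is fitted to the log of the (positivity-shifted) image over the
foreground by least squares; its exponential, normalized to unit mean over
the foreground, is the multiplicative field. Because the fit is a linear
projection the correction is idempotent. This deliberately replaces the
full histogram-sharpening N4 machinery with a small, testable estimator of
the same smooth multiplicative shading; the module boundary makes it
swappable.

**Frame selection** picks the postcontrast frame with maximal mean
intensity over the evaluation region (ties break to the earliest frame) and
subtracts the precontrast frame. Selection is computed, never hard-coded to
a frame index, so protocols with different numbers of postcontrast frames
are handled uniformly.

**Segmentation** uses spatial fuzzy C-means on the subtraction image with
c = 3 clusters (enhancing tumor / parenchyma / background), fuzzifier
m = 2, and a 3×3×3 neighbourhood: after each membership update, memberships
are reweighted by the neighbourhood-averaged membership raised to the
spatial weight (weight 0 recovers plain FCM). Cluster centers are
initialized from intensity quantiles, which makes the segmentation
invariant to affine intensity rescaling and removes any dependence on a
random initializer. The tumor mask is the brightest cluster thresholded at
membership 0.5, restricted to the 26-connected component containing the
seed point. The plain-FCM objective is non-increasing across iterations;
the spatial reweighting is applied after convergence checking on the
centers, so the same stopping rule governs both variants.

In the end-to-end pipeline, segmentation runs inside a bounding box around
the seed point where only two tissue classes are present, so the pipeline
uses c = 2 there and clusters a 2-mm-smoothed copy of the subtraction
image (features are always computed on the unsmoothed image). With the
generator's strong intratumoral texture (SD 60 against a 150-unit
contrast), a brightest-of-three-clusters rule on the raw image splits the
lesion across clusters and keeps only its bright blobs (Dice ≈ 0.65 against
ground truth); the two-class smoothed variant restores Dice ≈ 0.93 and
with it the planted direction of the heterogeneity change. The c = 3
default remains appropriate when segmenting whole volumes containing
background, parenchyma and tumor.

## Registration and Jacobian maps

Deformable alignment uses multi-resolution Gaussian-regularized demons
(symmetric-forces update; SimpleITK backend): 3 pyramid levels with shrink
factors 4/2/1, 50/30/20 iterations, update-field smoothing 2 mm, total-field
smoothing 1 mm, mean-squared intensity difference as the similarity metric.
The field lives on the baseline lattice and maps baseline coordinates to
follow-up coordinates, so tumor shrinkage yields Jacobians below 1.

The Jacobian map is computed in-package as `det(I + du/dx)` with central
differences taken in millimetres (spacing-aware; one-sided at the borders).
An identity field gives exactly 1. Non-positive determinants (folded
transformations) are counted, reported, and clamped to 1e-3 so that
downstream gray-level discretization stays defined. On planted isotropic
contractions of s = 0.8 the recovered mean endpoint error inside the tumor
is about 0.2 voxel and the mean Jacobian is within a few percent of s³;
recovery degrades for contractions much stronger than the planted
distributions, where demons regularization biases the field toward
identity.

Jacobian-map radiomics are computed over the *baseline* tumor mask, since
the map lives on the baseline lattice.

## Radiomic features

102 features per ROI in six families — shape (14), first-order (18), GLCM
(24), GLRLM (16), GLSZM (16), GLDM (14) — with IBSI-consistent definitions
and a frozen name registry so feature vectors align across runs and image
sources. Numerical conventions:

- **Discretization**: fixed bin count, 32 bins inside the ROI (a fixed
  bin-width mode is available); the in-mask minimum maps to level 1 and the
  mapping is monotone. Constant regions collapse to a single level and are
  flagged.
- **GLCM**: 13 unique 3D directions at distance 1, symmetric matrices,
  features computed on the direction-averaged normalized matrix.
  Degenerate single-level matrices return correlation-type features as 1.
- **GLRLM**: run counting along the same 13 directions; features on the
  direction-averaged count matrix.
- **GLSZM**: zones are 26-connected equal-level components.
- **GLDM**: a neighbour is dependent when its level differs from the
  centre by at most α = 0; the matrix column index is the dependence count
  plus one (the centre voxel), so dependence size is at least 1 and product
  weights such as large-dependence high-gray-level emphasis are
  non-degenerate.
- **First order**: energy uses no intensity shift (subtraction images are
  legitimately negative); entropy/uniformity use the discretized histogram;
  skewness/kurtosis are population-moment (biased) versions, kurtosis
  without the −3 excess convention.
- **Shape**: mesh volume and surface area from a marching-cubes surface of
  the slightly smoothed mask (Gaussian σ = 0.5 voxel suppresses the
  staircase inflation of the surface area); axis lengths are 4·√eigenvalue
  of the physical-coordinate covariance; maximum diameters use convex-hull
  pairwise distances.

Texture features are invariant to joint translation of image and mask;
shape features depend only on the mask and spacing.

## deltaRAD and design matrices

deltaRAD applies the relative net change to all 102 features. A baseline
feature exactly 0 makes the ratio undefined: the value becomes missing and
is median-imputed within the development arm. Design matrices exist for
five source sets — baseline, follow-up, deltaRAD, Jacobian, and fusion
(column concatenation of all four, 408 columns) — optionally appending
molecular subtype as indicator columns with luminal A as the reference
level. Standardization (and imputation) parameters are fitted on the
development arm only and applied unchanged to the testing arm; column
provenance is recorded so leakage can be audited.

## Modeling

The classifier is a Gaussian-kernel SVM. Feature ranking is SVM-RFE with
the kernel margin criterion: with dual coefficients held fixed, each
remaining feature is scored by the change in
`W² = Σ α_i α_j y_i y_j K(x_i, x_j)` when that feature is removed from the
kernel, and the least influential 10% are eliminated per round (step 1
reproduces exhaustive one-at-a-time elimination). Exact criterion ties at
the elimination boundary — duplicated columns — are eliminated together so
they occupy adjacent ranks; remaining ties break toward the earlier column.

Model selection adds top-ranked features one at a time (k = 1..10) and
tunes (cost, γ) by stratified 10-fold cross-validated AUC on the
development arm, with a fixed fold seed. The default search grid is cost ∈
{2⁻⁵..2¹⁰}, γ ∈ {2⁻¹⁰..2³} in powers of 2; full-cohort pipeline runs use a
coarser stride (2³) over the same range so an end-to-end analysis stays
desk-scale. Ties in CV AUC resolve toward fewer features, then smaller
cost, then larger γ. The winner is refit on the whole development arm and
applied once to the testing arm.

Evaluation reports AUC (trapezoidal rank rule), its Hanley–McNeil standard
error, and sensitivity/specificity/PPV/NPV at the Youden operating point
(maximum sensitivity + specificity; among ties the highest threshold).
Paired model comparisons use DeLong's test on the shared test-arm scores; a
paired-bootstrap alternative is available behind a flag.

## Problem sizes and numerical choices

Default cohort runs use n = 114 patients at 64³; the acceptance script uses
n = 60 with 10 development/testing re-splits, and test smoke runs use
n = 10 at 40³ — all are package choices to keep a full analysis at desk
scale. Replicated model comparisons re-split one simulated cohort into
development/testing arms rather than re-simulating and re-registering a new
image cohort per replicate; simulation and registration effects are already
averaged over 114 independent tumors within a cohort. The null-model check
runs on tabular feature cohorts with permuted labels, where image content
is irrelevant by construction.

## Known limitations

- The demons field under-recovers very strong contractions (volume ratios
  below ~0.4), so recovered Jacobians compress the planted group separation
  without changing its direction.
- The simplified bias corrector captures low-order smooth shading only; it
  is not a replacement for histogram-based correctors on real scanner data.
- The spatial-FCM segmentation assumes a unifocal enhancing lesion;
  multifocal disease would require seed-per-lesion handling that is out of
  scope.
- Feature definitions follow the IBSI formulations family-by-family but no
  claim of bitwise agreement with any specific radiomics toolkit is made;
  the brute-force oracles in the test suite are the reference.
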