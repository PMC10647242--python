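# Methods

`deltarad` implements a delta-radiomics survival workflow for paired
pre-treatment / early-follow-up CT of a primary lung tumor: texture features
are extracted from both scans, their change over the inter-scan interval is
turned into candidate biomarkers, and a staged Cox procedure selects and
evaluates a progression-free-survival (PFS) risk model.  Because the clinical
imaging data this kind of study uses is private, the package ships a
first-class synthetic cohort generator with a planted, recoverable hazard
signal; every stage of the pipeline is exercised and tested against it.

## Image preprocessing

Volumes are resampled to 1 mm isotropic spacing (trilinear for intensities,
nearest-neighbour for masks, via `scipy.ndimage.zoom`; the output grid maps
corner samples onto input corners).  Intensities are then Z-scored — mean 0,
population-SD 1 — over the whole image by default (`scope="roi"` is
available).  Normalisation precedes wavelet filtering; the order is
configurable.

The wavelet bank is a one-level separable 3D **stationary** (undecimated)
transform: every sub-band keeps the input grid, so the ROI mask applies to
all bands without resampling.  Band labels `LLL`..`HHH` give the per-axis
low/high-pass filter in axis order (x, y, z).  The family defaults to Haar
(the family is not dictated by the problem; it is fixed for reproducibility
and configurable), with symmetric padding to even axis lengths and cyclic
convolution.

## Feature catalog (593 per ROI)

Per band: 14 first-order statistics, 22 GLCM features, 16 GLRLM features and
13 slice-wise LBP features (65), over 9 bands (original + 8 sub-bands) = 585,
plus 8 mask-geometry features computed once: **593 named features**,
`<band>_<feature>` plus `Shape_*`.  Published per-family counts for this
catalog size are not available, so the 14/22/16/13 + 8 breakdown is an
engineering choice frozen in `catalog_feature_names()`; definitions follow
the IBSI formulations.

- **Discretization**: 32 equal-width bins over the ROI intensity range of
  each band (a common radiomics default; nothing in the published feature
  lists pins this choice down).  A constant ROI collapses to one level and is
  flagged, not rejected.
- **GLCM / GLRLM**: distance-1 co-occurrence and run-length matrices over the
  13 unique 3D directions (26-connectivity modulo sign); feature values are
  averaged over directions, which makes the aggregates exactly invariant to
  axis-aligned 90° rotations (property-tested).  GLCM matrices are
  symmetrised and normalised per direction.  Names that would collide with
  first-order ones use the IBSI "joint" prefix (`Joint_Energy`,
  `Joint_Entropy`, `Joint_Average`, `Joint_Variance`).
- **LBP**: rotation-invariant uniform codes, P=8, R=1, per axial slice, on a
  256-level quantisation of each slice (the 8-bit setting the operator was
  designed for; it also makes the diagonal bilinear samples exact on flat
  regions).  In-ROI codes pool into one 10-bin histogram; the 13 features are
  the normalised bins plus histogram mean, variance and entropy.
- **Shape**: volume, surface area (marching cubes on a Gaussian-smoothed mask,
  σ = 0.8 voxels, which suppresses the staircase overestimate — a voxelised
  sphere at 64³ recovers sphericity within 2%), surface/volume, sphericity,
  compactness (36πV²/A³), maximum 3D diameter, and elongation/flatness from
  the PCA eigenvalues of the voxel coordinates.

All matrix-based features are verified against brute-force pair-enumeration /
run-scanning oracles on ≤6³ integer phantoms to 1e-9.

## Reliability filtering and delta transforms

Test–retest reliability is emulated by re-extracting features from a
morphologically jittered copy of each mask (random boundary dilation/erosion,
interior untouched) for 30 subjects — a stand-in for a second reader.
Features are kept when ICC(2,1) (two-way random effects, absolute agreement,
single measure) exceeds 0.80; zero-variance features have undefined ICC and
are dropped with a warning.  The implementation is the ANOVA closed form and
is cross-checked against pingouin's ICC(A,1).

With pretreat value p, follow-up value f and inter-scan interval Δt (days):

| method | definition |
|---|---|
| `pretreat_only` / `follow_only` | pass-through |
| `delta` | (f − p) / p |
| `delta_time` | (1/Δt) · (f − p) / p |
| `delta_log_time` | (1/Δt) · (log f − log p) |

Undefined cells (p = 0, or non-positive log inputs — common for high-pass
band means) become missing values with a logged count; columns that are
entirely undefined are dropped at selection time, the rest are median-filled.
The percentage forms are exactly scale-invariant, the log form agrees with
the time-adjusted percentage form to first order in the relative change, and
both time-adjusted forms scale inversely with Δt (all property-tested).

## Imputation, selection, modelling

- **Laboratory missingness** is filled by an iterative random-forest imputer
  in the missForest style (median/mode initialisation, sweep columns in
  increasing missingness, stop when the normalised change in imputed values
  rises or after 10 sweeps; observed cells never altered), built on
  scikit-learn forests.
- **Clinical screen**: dummy-encoded covariates (reference level dropped; M
  stage kept ordinal) → univariate Cox p < 0.1 → one multivariate Cox fit,
  keep p < 0.1.
- **Radiomic screen** per delta method: univariate Cox p < 0.05 → iterative
  VIF pruning (recompute after each removal, drop the largest while any
  VIF > 5) → multivariate Cox on standardized features → keep the top 5 by
  |standardized coefficient| ("largest coefficients" is interpreted on the
  per-SD scale, since raw Cox coefficients are scale-dependent; ties at rank
  5 break lexicographically) → refit, retain p < 0.1 (all kept if none pass,
  logged).  Every elimination is recorded in a reproducible stage log.
- **Risk models**: Cox proportional hazards via lifelines (Efron ties),
  features standardized inside the fit with the parameters stored on the
  model for test-time reuse; non-convergent multivariate fits retry once with
  a small ridge penalty (logged).  The combined model is a single joint refit
  on the union of selected clinical and delta features.
- **Benchmark grid**: four selectors (Kbest = best univariate Cox p; Lasso /
  ElasticNet = Coxnet path, first alpha with ≥5 active coefficients; Ridge =
  penalised Cox magnitude ranking) × five learners (CoxPH, survival tree,
  random survival forest, fast survival SVM, gradient-boosted trees, all from
  scikit-survival), each restricted to 5 features selected inside the
  training fold, scored by IPCW AUC at the 383-day horizon under repeated
  stratified 5-fold CV.

## Evaluation

Harrell's C (risk ties count ½; via lifelines, oracle-checked against
exhaustive pair enumeration), and a cumulative/dynamic time-dependent AUC at
6/9/12/15 months (30.44 days/month) with inverse-probability-of-censoring
weights from the Kaplan–Meier censoring distribution of the training set —
authored as a weighted Mann–Whitney statistic and cross-checked against
scikit-survival's estimator.  Model comparison resamples subjects with
replacement (B = 100; degenerate replicates are redrawn, up to 10·B, to keep
B fixed) and applies a two-sided paired t-test per horizon.  Risk groups are
cut at the Youden threshold (max sensitivity + specificity − 1, IPCW-weighted
ROC on the *training* risk scores at the median training PFS; ties break
toward the lower threshold), then compared by Kaplan–Meier curves with
Greenwood bands, the two-group log-rank test, and Schoenfeld's power
approximation `Φ(|log HR|·√(d·p(1−p)) − z₁₋α/₂) + Φ(−|log HR|·√(d·p(1−p)) −
z₁₋α/₂)`, which equals α at HR = 1 and is monotone in |log HR| and the event
count.

## Synthetic cohort

Each subject carries an ellipsoidal tumor (radii 5–9 mm) filled with a
smoothed Gaussian field (per-subject correlation length) at contrast
c_pre = exp(N(0, 0.3)) on a N(0, 0.2) background with a +2 mean shift inside
the lesion.  The follow-up scan reuses the same field at contrast
c_pre·exp(shift), shift ~ N(0, 0.4): single-timepoint features see mostly the
baseline-contrast nuisance, while delta features isolate exp(shift) — the
planted signal.  The standardized shift enters the latent log-hazard with
coefficient `texture_effect_size` (default 1.0 per SD) together with clinical
effects (defaults ≈ the per-SD log hazard ratios of the published selected
clinical set: N stage 0.30, M stage 0.28, platelet 0.31, AST 0.27, total
protein −0.17).  Survival is Weibull proportional hazards (shape 1 =
exponential by default) with baseline median 383 days; censoring is uniform
on [0, c] with c calibrated by bisection to the target fraction (default
0.30); scan intervals are uniform over 6–16 weeks; laboratory values are
masked missing completely at random (default 30%).  Categorical covariate
marginals follow the demographic reference table shipped in
`deltarad/data/cohort_reference.csv`.

What the generator does *not* emulate: CT physics (beam hardening, noise
texture, contrast phases), metastatic lesions, tumor shrinkage or shape
change between scans (pre and post masks coincide), inter-scanner
heterogeneity, and realistic correlation among clinical covariates (they are
drawn independently).  Passing tests therefore demonstrate that the pipeline
recovers a planted texture-change signal under clean conditions — not that
the published effect sizes transfer to real cohorts, whose headline numbers
were computed on private hospital data and are out of reach at desk scale.

## Problem sizes and numerical choices

The default simulated cohort is 226 subjects on 24³ voxel fields of view at
1 mm — large enough for stable Cox fits and 70/30 evaluation while keeping a
full pipeline run in minutes on one CPU; the acceptance runs use n = 500 for
signal-recovery checks and n = 1000 for calibration checks at reduced image
sizes.  One pipeline seed fans out to per-stage child seeds
(`seed·1000 + stage`), making every stage independently reproducible;
identical configs reproduce bit-identical cohorts and reports.  Known
degenerate paths — constant ROIs, undefined delta cells, horizons with no
cases or no controls, folds without events, non-convergent fits — are either
flagged values or named errors, never silent.

One deliberate deviation from the natural first reading of the design: the
*censoring indicator* cannot be uncorrelated with latent risk when risk
predicts event time (high-risk subjects fail before their censoring time more
often), so independence is guaranteed — and tested — for the censoring *time*
draw instead.
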