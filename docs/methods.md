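# Methods

## Volumetry model

The measurement treats calcification as a thresholding problem on the
native CT grid. A spherical region of interest (ROI) of radius 12 mm is
anchored 20 mm posterior to the binary center of mass of the third
ventricle — a landmark-offset construction that avoids segmenting the
pineal gland itself. Voxels whose attenuation strictly exceeds 50 HU
inside the ROI are counted as calcified and multiplied by the voxel volume
|det A₃ₓ₃| (mm³ ≡ µL).

Deterministic geometric conventions, chosen where the construction is
genuinely underdetermined:

* **RAS+ everywhere.** Files are reoriented to RAS+ on load so "posterior"
  has exactly one meaning, the −y direction. The offset is applied along
  the scanner −y axis, not a patient-specific AC–PC axis; head tilt is not
  corrected. On tilted acquisitions the ROI therefore shifts with the
  head, a known limitation of any fixed-offset ROI.
* **Voxel-center membership.** A voxel belongs to the sphere (or to a
  phantom blob) iff its center lies inside. No partial-volume weighting:
  the rule is deterministic, exactly reproducible by an exhaustive scan,
  and makes noiseless phantom recovery exact rather than approximate.
  Partial-volume effects on real data appear as a boundary error of order
  (surface area × voxel pitch), which is why the sphere-voxelization check
  uses a 3% band at 1 mm pitch rather than exactness.
* **Strict inequality** at the threshold (> 50 HU), configurable.
* **Binary centroid.** The ventricle center of mass weights every
  labelled voxel equally; attenuation does not enter.
* **Silent clipping.** A sphere extending past the grid is clipped; the
  reported `n_roi_voxels` makes clipped measurements auditable.
* **No connected-component filtering.** Any supra-threshold voxel in the
  ROI counts, including non-pineal calcification that strays inside; on
  real data that is a visual-QC concern, not an algorithmic one.

Thresholding happens on the native grid; no resampling or interpolation
precedes it.

## Imaging phantoms

`make_phantom` builds an anisotropic grid (default 0.49 × 0.49 × 1.5 mm —
thin-slice axial head CT geometry) holding uniform soft tissue
(20 HU) with optional Gaussian noise, an ellipsoidal "third ventricle"
label, and spherical calcified inclusions. Blob intensity must exceed
50 HU and background + 4σ must stay below it, so the calcified/
non-calcified truth is unambiguous; a blob overlapping the ventricle is
rejected because the centroid truth would become ambiguous. The phantom
records both the analytic sphere volume and the voxelized truth (center
count × voxel volume); the two converge as spacing shrinks, which the
tests check at two resolutions. Phantoms deliberately omit skull, beam
hardening, streaks and partial-volume mixing: passing phantom tests shows
the geometry and bookkeeping are exact under the voxel-center model, not
that the 50 HU threshold is unbiased at calcification boundaries on real
scans.

## PSQI scoring

Component banding follows the standard instrument: latency minutes banded
≤15/16–30/31–60/>60 then combined with the "couldn't fall asleep within
30 min" frequency and rebanded 0/1–2/3–4/5–6; duration ≥7/6–<7/5–<6/<5 h;
efficiency = hours slept ÷ hours in bed × 100 (bed-to-rise interval taken
modulo 24 h) banded ≥85/75–84/65–74/<65%; the nine disturbance frequencies
summed and banded 0/1–9/10–18/19–27; medication used directly; the two
daytime-dysfunction ratings summed and banded 0/1–2/3–4/5–6. Total 0–21;
poor sleep ⇔ total ≥ 6. Missing items raise errors naming the item — no
imputation, matching interviewer-administered data collection. The
exhaustive 4⁷ component enumeration and single-item monotonicity
perturbations in the tests pin the implementation to the instrument's
published tables.

## Synthetic cohorts

`make_cohort` plants a fully known data-generating process:

* **Age**: truncated normal on [40, 95] whose *truncated* mean and SD are
  the requested 56.5 and 12.6 years (parent parameters solved
  numerically), matching a community cohort of adults aged 40+.
* **Sex**: Bernoulli, 57% female.
* **PGC volume**: gamma with mean 51 + 0.55·(age − 56.5) µL (floored at
  1 µL) and constant SD 53 µL. The gamma form gives the right-skewed,
  non-negative marginal real calcification volumes show (mean ≈ 51,
  SD ≈ 53.5, median ≈ 35 µL); the 0.55 µL/year slope reproduces a
  ≈ 11 µL difference between median-age strata. The distribution shape is
  a modelling choice — only the moments are calibration targets.
* **PSQI total**: a Gaussian linear predictor
  intercept + β_pgc·pgc + β_age·age + β_female·female
  (+ optional tertile-indicator effects, computed with the same
  rounding/tie rules the analysis uses so printed tertile coefficients can
  be planted directly), plus N(0, 2.7) noise, rounded and clamped to
  0–21. Defaults (intercept 2.7, β_pgc 0.004, β_age 0.04, β_female 0.25)
  give mean ≈ 5.3, SD ≈ 2.8.

Two consequences of the round-and-clamp outcome model are worth knowing.
First, a symmetric Gaussian with mean 5.3 puts ≈ 45% of mass at ≥ 6,
somewhat above the ≈ 40% a right-skewed empirical PSQI distribution
yields at the same mean; the generator prioritises matching the stated
moments over the quantile. Second, clamping at 0 compresses group
differences by a factor ≈ Φ((µ−0)/σ) ≈ 0.97, so planted coefficients are
recovered with a small known attenuation (≈ 0.015 at the default
calibration) — visible in the acceptance numbers and well inside the
recovery tolerance.

## Cohort analysis

* **Tertiles**: volumes are rounded to integer µL first, cut at the
  order statistics ⌈n/3⌉ and ⌈2n/3⌉, with all rows sharing a boundary
  value grouped into the lower tertile — hence integer cutpoints and
  (possibly) unequal counts. Label invariance under monotone transforms
  holds for integer-preserving transforms; transforms that merge rounding
  bins can change the split, a direct consequence of rounding first.
* **Models**: Gaussian identity-link GLM for the PSQI total, logistic
  regression for the poor-sleep class (log-odds reported, odds ratios
  derivable), tertile 1 referent, optional age + female adjustment.
  Classical (non-robust) variances, Wald 95% CIs, two-sided p-values —
  the default output of the GLM software family such analyses use. A
  constant outcome is fitted by the equivalent least-squares problem
  directly, since the IRLS scale estimate degenerates. Rank-deficient
  designs and complete separation raise errors naming the problem instead
  of returning unidentified estimates.
* **LOWESS**: implemented in-package as Cleveland's smoother — for each
  sorted x, a tricube-weighted linear fit over the nearest
  ⌈fraction·n⌉ points, with `iterations` bisquare robustness passes using
  6·median|r| scaling; defaults fraction = 2/3, iterations = 3. Owning
  the implementation fixes the neighbour-count convention so the
  brute-force per-point oracle can demand 1e-8 agreement; a cross-check
  against statsmodels' lowess (at a span where both use the same window)
  agrees to machine precision. Ties at a grid point fall back to the
  robust-weighted mean of the co-located points.
* **Interaction / mediation**: the age-by-tertile interaction is a joint
  Wald test on the two product terms; "mediation" is reported as the
  descriptive unadjusted-minus-adjusted coefficient difference, which
  obeys the exact finite-sample omitted-variable identity (auxiliary
  regressions of the covariates on the tertile dummies) — no bootstrap,
  no causal estimand claimed.
* **Median-age stratification**: per-stratum mean ± SD with a two-group
  linear-model p for continuous variables; chi-squared (no continuity
  correction) or Fisher's exact test when any expected cell is below 5
  for categorical ones.

## Problem sizes and test design

Phantom tests use grids of ≤ 48×48×32 voxels, where an honest triple-loop
oracle runs in under a second and agrees voxel-for-voxel with the
vectorized path. Statistical recovery uses 500 replicate cohorts of
n = 1,009 — the replicate mean pins bias at ≈ 0.01 precision, CI coverage
gets a binomial SE of ≈ 1%, and the joint-test null rejection rate is
checked against 5% ± 2%. All randomness flows through explicit seeds;
the suite and the acceptance script are deterministic end to end.

## Known limitations

* The ROI offset is applied in scanner coordinates; no tilt correction or
  AC–PC realignment.
* HU calibration is assumed, not verified, from the input files.
* The phantom's noise is white Gaussian; CT noise is correlated and
  non-stationary.
* The cohort generator's PSQI is a rounded Gaussian — adequate for moment
  calibration and effect planting, not a model of the discrete component
  structure (it does not generate item responses).
* Mediation is a coefficient difference, deliberately descriptive.
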