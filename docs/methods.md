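# Methods

This note records the models implemented in `eudgate`, the assumptions and
defaults of the synthetic cohort generator, the numerical choices, and what
the passing tests do and do not establish.

## Dose-effectiveness models

**gEUD.** The generalized equivalent uniform dose is the power mean of the
voxel doses over the structure, computed from the differential DVH. The
tumor exponent defaults to a = −20, which makes the measure track the
coldest percent-scale subvolumes: a 2% cold spot at 75% of prescription
pulls the gEUD of an otherwise uniform distribution to ~91%. Differential
masses are attributed to the lower bin edge (the cumulative curve drops at
the edge above a discrete dose level), so distributions whose dose levels
coincide with edges — uniform doses in particular — are represented
exactly, and `gEUD(uniform D) = D` holds to machine precision. Histogram
bins default to 0.1% of the maximum masked dose. A structure containing a
zero-dose voxel has gEUD 0 for a < 0 (the cold spot dominates completely);
this is returned with a warning rather than an overflow.

**EUD_SF.** The cell-survival EUD uses the linear-quadratic single-fraction
survival with fraction-size correction,
`s(d) = SF2^[(d/2 Gy)·(α/β + d)/(α/β + 2 Gy)]`, α/β = 4 Gy. A course is
modeled as the same per-fraction distribution delivered n times (n = 30 by
default); course survival is the volume-weighted mean of `s(d_i)^n`, and
EUD_SF is the total uniform dose with equal course survival, found by
Brent root-finding on the monotone log-survival (log-sum-exp is used so
the sum never underflows at realistic dose ranges). The primary source for
this model prints no equation, only its parameter values and citations; the
standard survival-based form above is adopted, and a switch
(`fraction_size_correction=False`) provides the plain `SF2^(d/2)` scaling
for sensitivity checks. Uniform input reproduces the total dose exactly,
with or without the correction.

**SF2 calibration.** The Poisson tumor-control condition
`exp(−N0·SF2^n) = TCP` is solved in closed form,
`SF2 = (ln(1/TCP)/N0)^(1/n)`. With TCP = 0.5, 60 Gy in 2 Gy fractions and
N0 = 1e8 uniform-density clonogens this yields SF2 = 0.534598229, which is
also the fixed acceptance target of `scripts/acceptance.py`.

**D_min** is the minimum voxel dose inside the mask (argmin ties broken by
the lowest linear C-order index), not a DVH percentile; D99.9/D99/D98/D50
are separate DVH-percentile operations. This distinction matters: on the
synthetic cohorts only D99.9 still tracks D_min over the coldest fractions,
while shallower percentiles sit back on the dose plateau.

## Geometry

The directed Hausdorff distance of CTV_i from CTV_plan equals the radius of
the minimal isotropic expansion of CTV_plan that contains CTV_i. It is
computed as the Euclidean distance transform of the complement of CTV_plan
(anisotropic spacing respected in mm) maximized over CTV_i voxels, which is
exactly the brute-force max–min voxel-center distance; an O(N²) oracle
verifies this equivalence exhaustively in the tests. The directed form is
implemented as defined — a CTV_i shrinking strictly inside CTV_plan has
HDD = 0; no symmetrization, no percentile variants.

Point features use world coordinates and trilinear interpolation of doses
and fields throughout (the interpolation order is a package choice; the
underlying definitions do not specify one). Inverse point mapping solves
`q + u(q) = p` by fixed-point iteration `q ← p − u(q)` (tolerance 0.01 mm,
up to 50–60 iterations), which converges whenever the warp's spatial
Lipschitz constant is below one.

The variance decomposition of deformation samples (per patient × fraction)
returns, per axis, the pooled within-patient SD (random component) and the
SD over patients of the per-patient means (systematic component). The
caller chooses what to feed it — raw vectors at one point, or differences
of vectors between two points, which is how the emulated clinical analysis
defines its components. No small-sample correction is applied; with 10
patients the per-axis systematic estimate itself carries ~24% sampling
error (SD-of-SD at n = 10), which is why the recovery test aggregates the
systematic component over axes (RMS) while testing the random component
per axis.

## Dose accumulation

The static-dose-cloud approximation is used throughout: dose is computed
once on the planning geometry and held fixed in space while the anatomy
deforms through it. The accumulated dose at planning voxel q is the mean
over fractions of the planned dose sampled at q + u_i(q), where u_i maps
planning to fraction geometry — i.e., uniform fractionation of the planned
course; hyperfractionated and conventional schedules collapse to the same
normalized quantity. There is no dose recalculation engine; the clinical
literature validates the approximation for deformations of this magnitude
via gamma analysis, and the package provides the same instrument: a global
3%/3 mm gamma with exhaustive lattice search within 3×DTA (a farther match
cannot pass, since its distance term alone exceeds 1), verified against a
whole-grid exhaustive oracle. Gamma normalization is global (a single
reference dose); voxels below a 10% threshold are excluded.

Field inversion solves `v(p) = −u(p + v(p))` by vectorized fixed-point
sweeps; the contract is a composition residual RMS below 0.1 mm, evaluated
where the pre-image stays inside the grid (and optionally restricted to a
caller's ROI — the inverse is not defined for voxels whose pre-image lies
outside the domain). Structure warping in the cohort generator uses
`warp_mask_band`: only voxels within max|u| + 2 mm of the mask surface can
change membership, so their pre-images are found pointwise and sampled
nearest-neighbour — the same resample through the inverse field at a
fraction of the cost.

## The synthetic cohort generator

The generator reproduces the *conditions* of the emulated clinical series,
not its images:

- **Cohort structure.** 10 patients; per-patient CTV volumes and examined
  fraction counts resampled (permuted) from the series' empirical values
  (149.3–344.2 cm³; 11–40 fractions, 218 in total).
- **Planning dose.** Prescription plateau on CTV + 5 mm margin with a mild
  planned overdosage inside the PTV (+0.5%/mm of depth, capped at 105%),
  then linear falloff with an anisotropic effective distance: per-patient
  cranio-caudal gradient drawn from 5–12.5 %/mm and axial gradient from
  1.5–6.25 %/mm. The resulting per-patient median normalized gEUD_i is
  ≈1.04, at the upper edge of the emulated series' 1.004–1.037.
- **Deformations.** The reported systematic (1.7/3.0/2.3 mm in x/y/z) and
  random (3.0/3.3/3.9 mm) components are statistics of *differences of
  deformation vectors between two CTV points*; the config uses that same
  scale, and per-point fields are scaled by 1/√2 so that two decorrelated
  points reproduce it. Each patient gets a fraction-constant systematic
  Gaussian random field; each fraction adds an independent random field.
  Fields are stationary (periodic smoothing of white noise with a 15 mm
  correlation length, normalized by the theoretical kernel norm), softly
  magnitude-capped (identity below 6 mm, saturating at 9 mm — residual
  deformations after online image guidance rarely exceed ~1 cm, and the
  cap bounds the worst-case warp gradient), and rolled off to zero over
  16 mm at the grid boundary (far anatomy is fixed by the setup). Every
  field is checked for a positive warp Jacobian; offending amplitudes are
  damped with a warning.
- **Excursions.** With probability 0.05 per fraction a localized Gaussian
  bump (amplitude 8–12 mm, width σ = 12 mm) displaces the CTV surface
  outward at a site clustered toward the cranio-caudal poles — where the
  emulated series localized its largest deviations and where the dose
  gradients are steepest. The bump is not attenuated by the boundary
  roll-off (it models an anatomical baseline shift at the target). Under
  these defaults 4–8% of fractions per seeded cohort fall below 93% of the
  prescribed gEUD, the per-fraction D_min of affected fractions drops to
  0.6–0.8 of prescription, and — the central robustness property — the
  accumulated gEUD of every patient stays at or above the prescription.
- **Grid.** 2 mm isotropic voxels on a 64³ grid by default. Arrays are
  indexed (z, y, x) with z cranio-caudal; all 3-vectors in the package
  follow that order.

**What the generator does not emulate:** CT/CBCT intensities, realistic
anatomy or organ boundaries, deformable registration errors, manual contour
corrections, tumor regression over the series, or dose-calculation effects
in heterogeneous lung tissue. Passing tests on these cohorts establish that
the *pipeline* is correct and that the qualitative mechanisms (focal cold
spots from margin-exceeding motion; averaging-out under accumulation;
D_min's dominance as a predictor) operate as in the clinical analysis —
they do not reproduce patient-level clinical numbers, which depend on
unavailable imaging.

**The tabular validation cohort** (`generate_feature_table`) is a separate,
fast generator for the regression studies: normalized gEUD is a noisy
monotone function of normalized D_min (flat plateau, steep fall below
0.75), with partially informative geometric features and per-patient
heterogeneity. It deliberately over-samples the steep limb (15% of
fractions against the ~5% clinical rate): it is a validation cohort for
identifiability on held-out patients, not an epidemiological one — at the
clinical rate the steep limb is too rare for a forest to learn at all.

## Cross-validated prediction

"Classifier" performance is measured as regression of the continuous
normalized gEUD. Fractions below 90% of prescription get sample weight 10,
those in 90–95% weight 2, all others 1. The random forest (500 trees, √p
feature subsampling, minimum leaf 5 — the reference implementation's
hyperparameters are unpublished, these are standard defaults) is trained
per leave-one-patient-out fold; variable importance is permutation
importance measured on each fold's held-out patient (data unseen by the
model, in the spirit of out-of-bag loss reduction) and averaged over folds.
The MLP (one hidden layer of 8 units, LBFGS) uses nested cross-validation:
per outer fold, 12 candidate networks are trained on random 6-of-9-patient
subsets and the candidate with the best correlation on the full outer
training set scores the held-out patient, which never enters training or
selection. Integer sample weights are applied to the MLP by row
replication (exact for integer weights). patient_id enters as one-hot
indicators over training patients; a held-out patient is all-zero (an
unseen category). An optional protocol adds the held-out patient's first
1–5 fractions to training and scores only fractions beyond the fifth.

Statistics: Pearson correlations carry Fisher-transform 95% CIs
(`tanh(atanh r ± 1.96/√(n−3))`); two models sharing the same ground truth
are compared with Steiger's pooled-r Z for dependent correlations; VE_cv is
the held-out `1 − SSE/SST` (negative for models worse than the mean);
stepwise polynomial fits retain the highest degree whose top coefficient is
significant, with a stop once the fit is numerically perfect (t-tests on
zero residuals are noise); Kruskal–Wallis, Spearman and Wilcoxon
signed-rank wrap the standard tie-corrected implementations, with an
all-values-identical Kruskal–Wallis input returning H = 0, p = 1 by
convention. Type-I error of the three tests is verified at the nominal 5%
over 2000 simulated null replicates.

## Numerical choices and degenerate inputs

- Argmin/argmax ties: lowest linear (C-order) voxel index, everywhere.
- Trilinear sampling clamps to the boundary value outside the grid; mask
  resampling is nearest-neighbour.
- `scalar_pdmin` with a zero-length reference direction returns 0 with a
  warning (degenerate worst-fraction deformation).
- Accumulating m identical fraction doses reproduces the plan to float
  round-off (≲1e-13 relative; summation is not bit-exact for m not a power
  of two) with no resampling blur.
- Problem sizes in the test suite: full-size cohorts (10 patients, 218
  fractions, 64³ grid) are used for the cohort-level properties; 32³–48³
  grids and 2–3-patient cohorts for structural unit tests; the regression
  studies run on the tabular cohort (218 rows).

## Known limitations

- The boundary roll-off and magnitude cap mean the generator cannot
  represent bulk translations larger than ~9 mm plus a 12 mm excursion;
  that regime (gross setup error) is outside the emulated conditions.
- gEUD with a = −20 is extremely sensitive to single-voxel minima; on 2 mm
  grids the voxelization of the warped CTV can shift a fraction's gEUD by
  a few tenths of a percent of prescription. Tests use tolerances
  accordingly.
- The per-axis systematic deformation SD cannot be verified to better than
  ~24% from 10 patients; see the variance-decomposition discussion above.
- The gamma module scores on the voxel lattice (no sub-voxel refinement);
  this is exact with respect to its own lattice definition and is what the
  oracle-equivalence test verifies.
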