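# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pasmap`, and what the synthetic validation does and does not show
about real data.

## The PAS statistic

For each in-mask, non-midline voxel *v*, Pearson correlations with every
other in-mask non-midline voxel are computed over the retained timepoints.
Correlations not strictly greater than `r_threshold` (default 0.2) are
discarded; since the threshold is positive this also removes all negative
correlations, whose interpretation in BOLD connectivity is contested.
Survivors are averaged separately over same-hemisphere targets (excluding
the seed itself) and opposite-hemisphere targets, each mean is Fisher-z
transformed, and PAS = FC_inter − FC_intra.

Decisions the definition leaves open, and what this package does:

- **Order of mean and transform.** The default transforms the mean
  correlation, `z(mean r)`; `combine="mean_of_z"` averages the transformed
  correlations instead. Both are implemented and both are covered by the
  brute-force oracle, because the source method is ambiguous between them.
- **Threshold semantics.** Strictly greater than (`r > 0.2`); a
  correlation exactly at the threshold is excluded. The positive-only rule
  is logged as redundant whenever the threshold is positive.
- **Hemisphere assignment** is by the sign of the world x coordinate
  through the affine (RAS convention), never by voxel index, so any origin
  works. Voxels exactly on the x = 0 plane are labeled midline and by
  default excluded both as seeds and as targets; they can instead be
  assigned to one hemisphere.
- **Undefined voxels.** A voxel where one side has no surviving
  correlation gets NaN (with a zero survivor count) rather than a silent
  zero; such voxels are excluded from group statistics listwise and their
  per-subject counts are reported. By default a voxel enters group
  analysis only if it is defined in every subject.
- **Unequal hemisphere sizes** are handled with plain per-side means; no
  reweighting by voxel counts.
- **Numerical guard.** A surviving mean of exactly 1 (degenerate duplicate
  series) is clipped to 1 − 1e−12 before `atanh`, yielding a large finite
  value instead of infinity.

The engine computes each seed's correlation row as a matrix–vector product
over standardized series, one seed at a time; `chunk_size` only bounds
buffer memory, so chunked and unchunked runs are bit-identical (asserted
in tests — batched GEMM calls do *not* guarantee this, which is why the
row-by-row form was chosen). An O(V²) brute-force reference
(`pas_map_bruteforce`, per-pair `np.corrcoef`) ships in the package and
the two must agree to 1e−10 on small volumes.

**A note on the null symmetry.** PAS is *not* zero for a volume whose
series are literally mirror-symmetric: the seed's mirror twin contributes
an r = 1 correlation to the inter side while the intra side excludes the
seed itself, so PAS is strictly positive there. The correct null symmetry
is exchange-invariance of the correlation structure; the test suite
constructs exactly equicorrelated volumes (orthonormal-component
construction, every pairwise r equal to machine precision) and verifies
|PAS| < 1e−10 everywhere.

## Preprocessing

Fixed default order: discard 10 volumes → 4 mm FWHM Gaussian smoothing →
linear detrend → ideal FFT band-pass 0.01–0.08 Hz → nuisance regression →
scrubbing. Motion realignment and template registration are assumed done
upstream. Choices:

- **FD** is the Power scalar: summed absolute frame-to-frame translation
  differences plus 50 mm (configurable) times the summed absolute rotation
  differences; fd[0] = 0 by convention. Mean FD is computed on the
  *pre-scrub* trace because it serves as a per-subject covariate.
- **Scrubbing** deletes frames (threshold 0.2 mm, one back and two forward
  neighbors, windows clipped at the ends) rather than regressing spikes;
  deleted frames are recorded in `timepoint_keep` so correlations and any
  frame-indexed covariates stay consistent.
- **Filter** is an ideal frequency-domain mask (band edges inclusive),
  matching common resting-state toolbox behavior, not an IIR design.
- **Nuisance design**: intercept, WM mean, CSF mean, and the Friston-24
  expansion (6 parameters, their one-frame-back values, both squared).
  Rank deficiency raises an error naming the collinear columns.
- **Smoothing** truncates the Gaussian kernel at 6σ so the discrete kernel
  matches the closed form to below 1e−6.

## Synthetic cohort generator

Each gray-matter voxel's series is a weighted sum of band-limited
(0.01–0.08 Hz) unit-variance latents — one global bilateral signal, one
per-hemisphere network signal — plus spatially smoothed, per-voxel
re-standardized white noise, with weights chosen so total variance is 1.
With no effects this yields exact construction correlations
`base_inter_r = 0.30` between hemispheres and `base_intra_r = 0.35`
within, both above the 0.2 threshold so survivor selection stays mild.
Values were chosen once as representative of band-passed gray-matter BOLD
correlation levels; the band-limited construction means the planted
structure survives the band-pass filter.

Planted effects perturb weights for region voxels of one group:
`raise_intra` (strength *s*) raises that region's same-hemisphere
correlations by *s*, lowering PAS; `raise_inter` gives region voxels
weight on the contralateral network latent, raising opposite-hemisphere
correlations by *s* and raising PAS. Residual noise variance absorbs the
weight increase; if it would go negative the implied correlation
structure is not positive semi-definite and generation fails naming the
offending effect (the feasibility bound is roughly s ≤ 0.13 at the
default baselines).

Toy tissue compartments (a central deep-white ellipsoid and two
ventricle-like midline balls) carry their own nuisance latents plus noise
and no neural signal; they are excluded from the analysis mask. This is
what makes WM/CSF regression meaningful on synthetic data: it removes
genuine nuisance without destroying the neural latents.

Motion traces are slow 6-parameter random walks (step SDs 0.01 mm /
1e−4 rad, giving mean FD ≈ 0.04 mm as in the emulated cohort) with rare
level-shift spikes (rate 0.001/frame, amplitude 0.25–0.8 mm), so a spike
produces one FD exceedance and a 4-frame scrub window; the expected ~1
scrubbed frame per subject matches the emulated cohort's summary.
Clinical scores are drawn per group from the cohort profile's normal
model truncated at 0; for patients the means sit several SDs above zero,
so truncation bias is negligible (largest for the controls' near-zero
scores, where it slightly raises means — visible only in the third
decimal of simulated group t statistics).

What the generator does **not** emulate: hemodynamic response shape,
cardiac/respiratory physiology, anatomical geometry, spatial
nonstationarity, and site/scanner effects. Passing tests therefore
demonstrate the *statistical machinery* is correct and calibrated, not
that effect sizes transfer to real cohorts.

## Group inference and cluster correction

Voxel-wise one-sample and covariate-adjusted two-sample t tests are plain
GLMs solved by normal equations, vectorized across voxels (covariates are
centered; the group coefficient is patients − controls; df = n − rank).
Zero-residual-variance voxels report a capped t (±1e6) with a warning.

Cluster correction follows the standard Gaussian-random-field recipe:
per-axis smoothness (FWHM) estimated from the spatial first differences of
unit-normalized residual maps; RESEL count = analyzed voxels / ∏FWHM; the
voxel threshold is two-sided by default (each sign thresholded at
voxel_p/2 one-tailed, Gaussianized via the normal quantile, clustered
separately at 26-connectivity — configurable to 6/18, which can only
change cluster merging, never the suprathreshold set); each cluster's
corrected p uses the expected-Euler-characteristic cluster-size
approximation `P = 1 − exp(−E[m]·exp(−β k^{2/3}))` with the expected
cluster count doubled for the two signs. Small-sample corrections to the
smoothness estimator are omitted; on desk-scale grids the approximation
runs conservative, which the null simulation confirms (observed
false-positive cluster rate ≈ 0.015 per map at the nominal 0.05 level).
A permutation-based correction (max cluster extent over relabelings)
ships as an assumption-light cross-check.

## Clinical statistics

Group comparisons use the equal-variance pooled t — chosen because the
emulated cohort's printed t values are reproduced by the pooled form from
the printed summaries (e.g. severity total 25.28 recomputed vs 25.27
printed), whereas Welch gives ~25.9; Welch remains available by flag.
Region-by-score Pearson correlations use the exact t-transform p value
(df = n − 2) with Bonferroni correction over the full family
(7 × 3 = 21 tests → α/21 ≈ 0.00238).

## Classification

Per-region leave-one-out cross-validation: for each held-out subject,
feature standardization and hyperparameter selection (stratified inner
k-fold grid search) happen on the training fold only; the confusion matrix
accumulates over folds; patients are the positive class. The default is an
RBF kernel with the libsvm-style grid C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} and
nested 3-fold selection. For **single-feature** regions the simulation
studies use the linear kernel with a compact C grid and 5-fold inner CV:
an RBF kernel on one dimension adds capacity that only inflates selection
variance (measured: linear reaches 77.0% mean LOOCV accuracy on a
1.5-pooled-SD planted shift at n = 78, versus ~76% for RBF variants, with
a per-cohort P(accuracy > 70%) of 0.94 — statistically indistinguishable
from the Bayes-optimal rule's 0.94 at that effect size and sample size).
On permuted labels the procedure averages ~44–45% accuracy, not exactly
50%: LOOCV with nearly balanced classes is pessimistically biased because
removing one subject tilts the training majority against the held-out
class. Both behaviors are asserted in the test suite; because even the
optimal rule exceeds 70% in only ~94% of cohorts at this effect size, a
hard "90% of 50 simulations" detection bar fails occasional seed draws by
sampling error alone.

Fitting uses scikit-learn's low-level libsvm binding when available
(identical solver, ~10× less per-call overhead); a test asserts exact
prediction equivalence with the public `SVC` estimator across random
problems, and the public estimator is the fallback.

## Problem sizes

The default grid is 20 × 24 × 20 at a nominal 3 mm (≈ 3,700 analysis
voxels), 240 timepoints at TR 2 s, 40/38 subjects. Simulation studies in
the test suite run at reduced scale — 12 × 14 × 12 grids (≈ 700 voxels),
120 timepoints, 20/20 subjects for effect-recovery studies; 16³ grids for
cluster-level null calibration (500 maps); 200 permutation cohorts for
classifier calibration — sizes chosen so the full suite completes in a
few minutes while keeping every check adequately powered. Planted
strengths 0.035 (intra) and 0.040 (inter) were calibrated once by Monte
Carlo to produce a 1.5-pooled-SD group difference in region-mean PAS
under those reduced-scale conditions.
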