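# Methods

This note documents the models, conventions and numerical choices behind
`vesselmorph`, and what the synthetic generators do and do not establish.

## Imaging substrate and conventions

All volumes are 3-D arrays on an anisotropic grid (`GridSpec`: shape, spacing
in mm, origin). Voxel indices are 0-based; the world coordinate of voxel
`(i,j,k)` is `index * spacing + origin`. Volumes are assumed co-registered in
subject space: on NIfTI read, spacing and translation are taken from the
header/affine and any rotational component is ignored with a warning
(registration is out of scope). Reference spacings are 0.7 mm isotropic for
the angiography grid and 1.0 mm isotropic for the structural grid.

## Morphometry chain

**Atlas refinement.** A segmented voxel is removed when its occurrence
probability in the probabilistic vessel atlas is *strictly below* the
threshold (default 1%), so voxels at exactly the threshold survive. The
operation is anti-extensive (never adds voxels) and idempotent.

**Thinning.** Centerlines come from iterative topology-preserving thinning
with 26-connected foreground and 6-connected background. Each iteration
visits the six border directions in turn; candidates are border voxels of the
current direction with more than one foreground neighbour that are *simple*
— deletable without changing topology. Simplicity uses the standard
characterization: exactly one 26-connected foreground component among the 26
neighbours, and exactly one 6-connected background component within the
18-neighbourhood touching a face neighbour. Candidates are deleted
sequentially, re-checking **both** simplicity and the endpoint guard on the
current image. The guard re-check matters: with the guard frozen at
candidate-collection time (as in at least one widely used implementation), a
same-pass deletion cascade can consume a thin ribbon end-to-end, collapsing
an off-center cylinder to a single voxel or to nothing. Thinning is purely
combinatorial and ignores voxel spacing (documented asymmetry: radii are
metric, the skeleton is not).

**Radii.** The Euclidean distance transform is exact under anisotropic
spacing (`scipy.ndimage.distance_transform_edt` with the grid spacing as
sampling). The radius at a centerline voxel is its distance to the nearest
*background voxel center*, with no half-voxel correction. Against a tube of
true radius r this overshoots by roughly half a voxel (the nearest background
center sits just outside the surface); recovery tolerances in the tests are
`spacing/2 + 1 voxel`, and the error shrinks monotonically with grid
refinement. Tube caps are excluded from radius assertions — end effects are
not part of the measurement's contract.

**Regional summaries.** Artery density is the voxel-count ratio
(equivalently volume ratio on a single grid) of refined segmentation to flow
territory, as a percentage; it uses the full segmentation. Mean radii use
*only centerline voxels* — full-mask averaging would be dominated by large
arteries. Proximal/middle/distal sub-territory labels are unioned (by name)
before any measurement. A region containing no centerline voxel yields a
missing value (NaN), never a silent zero; downstream model fits delete rows
listwise with a logged count. A segmentation annihilated by refinement
produces all-missing measurements and an explicit QC flag. Intracranial
volume is foreground count x voxel volume / 1000 (cm^3).

## Statistical layer

**Preprocessing.** Responses are min-max normalized to [0,1]; predictors are
centered and scaled (sd with ddof=1). Both transforms are estimated on the
training rows only and re-estimated inside every leave-one-out fold —
anything else leaks the held-out row. Held-out values outside the training
range map outside [0,1] and are deliberately not clamped.

**Kernel PLSR.** The fit uses the Dayal–MacGregor kernel algorithm on the
cross-product matrices X'X and X'Y of the (internally centered) preprocessed
matrices, with per-component deflation of X'Y; coefficients accumulate as
`B_a = B_{a-1} + r_a q_a'`, predictions carry the intercept
`ybar + (x - xbar) B`. Centering both matrices matches the reference
behaviour of the R `pls` kernel implementation; min-max normalization alone
leaves the response uncentered, and without the intercept even a noiseless
linear response cannot be predicted exactly. At k = rank(X) the model equals
OLS; at smaller k it matches an independent NIPALS implementation to 1e-6
(both properties are tested). If X'Y deflates to numerical zero before k
components, the remaining components freeze (coefficients stop changing)
rather than erroring — the public fit still rejects k beyond rank(X).

**Leave-one-out machinery.** Each fold's preprocessed cross-products are
obtained by rank-one downdates of the full-data sufficient statistics
(sums, X'X, X'Y, plus the two smallest/largest response values per column
for O(1) fold min/max), so n refits cost O(n p (p+q)) rather than
O(n^2 p q). The per-(k, response) RMSE is computed on each fold's normalized
scale; the chosen k minimizes the response-averaged RMSE with ties to the
smaller k. The result is invariant to row order.

**Jackknife inference.** The coefficient variance is the Tukey jackknife over
the n leave-one-out refits, `(n-1)/n * sum (b_i - b_mean)^2`, with p-values
from a t distribution with n-1 df. Because each fold re-estimates the
transforms, fold coefficients are first mapped to the raw-units scale
(response units per predictor unit — invariant to the fold transforms)
before the variance is taken, and the standard error is mapped back to the
full-data normalized scale. Without this, the per-fold min-max jitter
inflates the variance of genuinely strong effects. Cells with zero jackknife
variance but nonzero coefficient report a p at the machine floor, with a
warning. Calibration: the null type-I rate at nominal 0.05 lies within
[0.03, 0.07] in a 500-rep simulation (tested).

**MANCOVA.** Wilks' lambda for a binary group factor after adjusting for
covariates (age, sex), computed from the error and hypothesis SSCP matrices
of the multivariate linear model, with Rao's F approximation. With one
response this reduces exactly to the ANCOVA F-test; with several it matches
`statsmodels` MANOVA to numerical precision (both tested). Post-hoc:
per-response ANCOVA with the same covariates; the Bonferroni factor is fixed
at 24 regardless of the response count, so significance requires raw
p < 0.05/24 ≈ 0.002. Note what Bonferroni guarantees: family-wise error
≤ 5% per analysis — across many repeated analyses occasional null flags are
expected, and the acceptance test bounds them binomially rather than
asserting zero. Adjusted group means are least-squares means (fitted values
at the sample covariate means) with standard errors from the coefficient
covariance.

**Quantile LOESS.** At each of 100 grid points (configurable) within the
observed age range, the span-nearest neighbours (default span 0.75) are
tricube-weighted and a local-linear fit minimizes the pinball loss for each
of the 25th/50th/75th quantiles — solved exactly as a linear program
(HiGHS). Windows with fewer than 5 contributing points yield a missing
value. Curves are re-sorted per grid point afterwards, so quantiles never
cross. Coverage between the 25th and 75th curves is 0.50 +/- 0.05 on
Gaussian data at n = 2000 (tested).

**Modeling choices.** Sex is coded M = 1, F = 2; drinks-per-day enters as the
ordinal 0-5 category code, not dummy-expanded. p-values of the three PLSR
models are reported unadjusted for multiple comparisons. Nonlinear (e.g.
J-shaped alcohol) effects are out of scope — a linear latent-component model
cannot represent them.

## Synthetic generators: what they emulate, what they do not

**Tube phantoms.** Vessels are capsules (cylinders with spherical caps):
a voxel is foreground iff its *center* lies within the radius of a segment
axis (inclusive) — the simplest defensible rasterization, and the one the
radius-recovery tolerances are calibrated against. The toy atlas is 1.0 on a
one-voxel-dilated capsule and 0.005 elsewhere; optional noise voxels are
single isolated (26-disconnected) foreground voxels placed where the atlas is
below 1%, so the refinement rule provably removes exactly them. Territories
are a six-box partition (L/R halves x three bands); artery masks are small
boxes on the tube midpoints; the intracranial mask is an inscribed ellipsoid.
The stylized 12-artery subject phantom gives each artery twice its
population-mean radius (so the thinnest is resolvable at 1 mm spacing), a
log-normal per-subject radius jitter (default sd 4%), and a small random
tilt — grid-aligned tubes would take a single quantized distance value along
the whole centerline. The fetal-PCA variant is emulated at the image level by
rescaling the basilar (smaller) and right internal carotid (larger) radii by
the observed group-mean ratios. Not emulated: MRA intensities, bifurcating
trees, curvature/tortuosity, segmentation errors other than isolated noise.

**Cohorts.** The nine risk factors are drawn from a latent multivariate
normal whose marginals match a large population imaging study (age
50.2 ± 13.8 y, 54.4% female, heart rate 70.6 ± 10.4 bpm, systolic BP
126.5 ± 17.1 mmHg, BMI 27.5 ± 4.4, WHR 0.88 ± 0.09, ICV 1402 ± 136 cm^3,
smoking 9.6 ± 13.4 y floored at 0, drinks categories 7.1/71/18.2/2.8/0.7/0.2
%). Sex and drinks are discretized by thresholding their latent normals at
the category frequencies. The correlation structure is this package's choice
(obesity markers correlate, blood pressure rises with age, ICV and WHR track
sex); no published value constrains it. The 24 responses are linear in the
standardized predictors plus independent Gaussian noise
(`Y = mean + Z B + E`), with default effects sign-consistent with the main
epidemiological findings and zero for smoking/alcohol; default residual
scales are ~15% of the mean for densities, 0.08 mm for territory radii and
0.12 mm for artery radii. A green recovery test therefore establishes that
the estimator recovers *linear* effects under *Gaussian* noise with
*correctly specified* predictors — not that real arteries behave linearly.

## Determinism and orchestration

One integer seed per spec/run; all stochastic draws flow from it
(per-subject streams via `SeedSequence.spawn`). Re-running a config
reproduces every CSV byte-for-byte. The run manifest records the software
version, the full config, the chosen component count and row count per PLSR
model, and a SHA-256 content hash of every subject mask. Variant subjects
are excluded from the PLSR models and quantile curves but included in the
MANCOVA; a run with no variant subjects (or too few complete rows for 24
responses) skips the MANCOVA with an explicit notice instead of failing.
Report percentages are rounded half-up to one decimal.

## Known limitations

- Radii measure the segmented lumen only; wall thickening or plaque is
  invisible to the method by construction.
- The EDT radius convention overshoots by up to ~half a voxel; no sub-voxel
  correction is applied.
- The thinning is implemented in Python; it is comfortable for the phantom
  scales tested (tens of thousands of foreground voxels) but not tuned for
  full-resolution whole-brain segmentations.
- Quantile LOESS solves one LP per grid point per quantile; at n = 2000 and
  100 grid points a three-quantile fit takes tens of seconds.
- The MANCOVA assumes a binary group and uses the ANCOVA group term for
  post-hocs (not estimated-marginal-means contrasts); the two coincide for a
  binary factor in a linear model.
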