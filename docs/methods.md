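# Methods

`wmlpredict` re-creates, at desk scale and on synthetic phantoms, an analysis
chain that asks whether the *spatial pattern* of white matter lesions (WMLs)
carries information about cognition beyond total lesion burden: segment
lesions from FLAIR/T1 images with a supervised KNN classifier, predict each
neuropsychological score from the voxelwise lesion maps with relevance vector
regression (RVR) under cross-validation, test significance by permutation,
and interpret the fitted model by aggregating its voxel weights over an
atlas of white matter regions.

## 1. Phantom cohorts

All experiments run on cohorts produced by `wmlpredict.phantom`.  The
generator is first-class, tested code: its job is to realize the statistical
structure the analysis assumes, so that recovery of that structure is a
meaningful check of the pipeline.

**Geometry.** A 48x56x48 grid at 2 mm isotropic resolution holds an
ellipsoidal "brain", two periventricular CSF slabs ("ventricles"), a
cerebellum used as the exclusion region, and 12 white matter regions (6
left/right pairs of boxes: tapetum, posterior corona radiata, posterior
thalamic radiation, anterior corona radiata, superior longitudinal
fasciculus, anterior limb of the internal capsule).  This is a desk-scale
stand-in for a 2 mm standard space with a 48-region white matter label
atlas; regions are painted sequentially and never overlap.

**Lesions.** Each subject's lesion mask is a union of connected blobs grown
from seeds drawn from a probability field `exp(-d/lambda)` where `d` is the
distance (mm) to the ventricles and `lambda` = 8 mm — lesions are
periventricular and confluent, which also gives the KNN segmenter spatial
coherence to exploit.  The per-subject target volume is log-normal (median
6 ml, log-SD 0.65, clipped to 1–42 ml, matching a typical elderly cohort
range of roughly 1–40 ml) with a positive log-linear age slope (0.045 per
year over ages 62–80) that yields a sample age–volume correlation near
r = 0.3 at n = 150–200.  Blob growth stops exactly at the target count, so
reported volume = voxel count x voxel volume always.

**Intensities.** Brain tissue mean 100, ventricle CSF dark on both channels,
lesion contrast +35 on the FLAIR-like channel and −25 on the T1-like
channel, Gaussian noise SD 3.  There is deliberately no partial-volume
modelling, bias field, or k-space artefact: segmentation on these phantoms
shows the classifier machinery is correct, not that it would reach the same
Dice on clinical data (real FLAIR boundaries are far harder).

**Scores.** Each synthetic test is `score = intercept + sum_r beta_r *
load_r + noise`, `load_r` = lesion volume (mm^3) in region r.  Defaults
define three tests: a global-cognition test (declines with tapetum load), a
memory test (declines with posterior thalamic load), and a timed test
(rises with tapetum load, noise SD 0.5).  The timed test is the designated
low-noise recovery target: its beta is positive because the region
*contribution* convention (below) is built on positive weight mass, so a
test whose score increases with lesion load is the one whose ground-truth
regions must surface at the top of the table.

**Diffusion maps.** FA 0.45 healthy with −0.06 inside lesions; MD/AD/RD
0.75/1.20/0.55 (units of 1e-3 mm^2/s) with +0.15/+0.25/+0.20; noise SDs
0.04–0.05.  The perturbation ordering AD > RD > MD > FA (relative to noise)
is a property of the generator, mirroring the ordering the analysis is
meant to detect; it is not a biological claim.

**Randomness.** Every subject is generated from an independent substream
`default_rng([seed, subject_index])`, so changing one model parameter (e.g.
the volume median) changes each subject's draw monotonically and cohorts
are bit-reproducible given the seed.

## 2. KNN lesion segmentation

Features per in-brain voxel: z-scored T1 and FLAIR intensities plus the
three voxel-centre coordinates, z-scored the same way and multiplied by the
spatial weighting (default 1).  Z-scoring uses the population-SD
(divide-by-n) convention within the brain mask, per subject.  Putting the
coordinates on the same unit-variance footing as the intensities is a
deliberate choice: with raw millimetre coordinates (range ~100) against
unit-variance intensities, every nearest-neighbour distance is purely
spatial and the classifier is blind to contrast — a spatial weighting of 1
then means "location counts as much as intensity".

Training points are pooled across the labelled subjects and sampled without
replacement: 2000 lesion points from manual-mask voxels, 10000 non-lesion
points from any in-brain non-lesion voxel ("fixed + unbalanced"); a class
with fewer eligible voxels contributes all of them with a logged warning.

A voxel's lesion probability is the lesion fraction among its k = 40
nearest training points (k is not dictated by the published recipe; 40 is a
stable mid-range default for 12000 training points and is configurable).
Neighbours come from a k-d tree; any query whose k-th and (k+1)-th
neighbour distances coincide exactly is re-resolved by exhaustive search
with ties broken toward the lower training-point index, so probabilities
are exactly reproducible multiples of 1/k.  The lesion mask keeps voxels
with probability strictly greater than 0.9 (a boundary voxel at exactly 0.9
is excluded), and lesion volume is mask count x voxel volume / 1000 (ml).

## 3. Relevance vector regression

The predictor of each score is a linear-kernel RVR: `f(x) = sum_n w_n
(x . x_n) + b` with independent zero-mean Gaussian priors `w_n ~ N(0,
1/alpha_n)` and type-II maximum likelihood over the `alpha_n` and the noise
variance `sigma^2`, iterating the standard re-estimates

    Sigma = (sigma^-2 Phi^T Phi + A)^-1,   mu = sigma^-2 Sigma Phi^T y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2,   sigma^2 <- ||y - Phi mu||^2 / (N - sum gamma)

with pruning at `alpha > 1e9`, convergence at `max |delta log alpha| <
1e-3`, at most 500 iterations, `alpha_init = 1/N^2`, `sigma^2_init =
0.1 var(y)`.  The bias is an extra basis column with a small fixed
precision (1e-6), never pruned or re-estimated.  The linear kernel is
forced by the analysis itself: only a linear-in-features predictor
back-projects onto a voxel weight map `w_vox = sum_n mu_n x_n` with
`f(x) = x . w_vox + b` holding exactly, which the interpretation stage
requires.

Two numerical decisions matter in practice and are worth stating plainly:

* **Unit-norm basis normalization (default on).**  Kernel columns are
  rescaled to unit Euclidean norm inside the hyperparameter loop; weights
  and precisions map back to raw units exactly afterwards.  This is a pure
  reparameterization, but without it the dot products of thousands of
  voxels give kernel columns norms in the hundreds, `alpha_init` is then
  vacuously weak at any fixed value, the first posterior interpolates the
  targets, the noise variance collapses, and no basis function is ever
  pruned.  With normalization the classic behaviour reappears (targets
  independent of structured features prune to a handful of relevance
  vectors with `sigma^2 ~ var(y)`).  Disabling it (`normalize_basis=False`)
  interprets `alpha_init` on the raw basis, which is the mode in which the
  frozen-hyperparameter fit equals the ridge closed form
  `(Phi^T Phi + alpha sigma^2 I)^-1 Phi^T y`.
* **Monotone evidence safeguard.**  The MacKay re-estimates above are fast
  but not guaranteed to increase the marginal likelihood; each iteration
  therefore evaluates the evidence at the candidate update and, if it
  decreased, substitutes the EM update (`alpha_i = 1/(mu_i^2 + Sigma_ii)`,
  `sigma^2 = (||r||^2 + sigma^2 sum gamma)/N`), which shares the same fixed
  points and is provably non-decreasing.  The recorded evidence path is
  non-decreasing to numerical tolerance on every problem we test.

A known structural limit, demonstrated in the test suite: a *sample-space*
kernel method cannot exploit feature-space sparsity in uncorrelated
features.  If 5 of 2000 iid voxels carry the signal, the best achievable
out-of-sample correlation for any kernel-ridge-family predictor is near
zero (the truth has almost no projection on the span of N training maps).
RVR prediction works on lesion data because lesion maps are strongly
spatially correlated — the signal lives in high-variance directions of the
kernel.  Stochastic tests of sparsity and recovery therefore use
correlated (lesion-map-like) feature designs.

## 4. Evaluation and permutation testing

Subjects are split into 7 near-equal folds by seeded shuffle; each fold's
model is fitted on the complement (the full Gram matrix is computed once
and sub-indexed, which is exactly equivalent) and predicts its held-out
subjects; metrics are computed on the pooled out-of-fold vector, matching
the one-scatter-per-test presentation convention rather than averaging
per-fold metrics:

    CORR      Pearson correlation of observed and predicted scores
    MSE       (1/N) sum (y_n - f(x_n))^2
    norm MSE  MSE / (y_max - y_min)

Significance: the target vector is permuted and the *entire*
cross-validated pipeline is retrained per permutation (1000 by default;
tests and the acceptance script use 99–199 with the reduced count logged).
P-values use the add-one rule `p = (1 + #extreme)/(1 + B)` — never zero,
floor `1/(B+1)` — with high CORR extreme for CORR and low MSE / norm MSE
extreme for the error metrics.  A permuted target can prune every basis
function and yield constant predictions, for which CORR is undefined; such
null draws are recorded as CORR = 0 (no linear dependence).  Calibration
under a true null is verified at reduced size (21 subjects, 4 folds,
99 permutations, 200 repetitions — sizes chosen to keep the check cheap;
permutation validity does not depend on them).

## 5. Weight interpretation

Per fold, the fitted model is back-projected to a voxel weight map and
aggregated per atlas region: a region's *contribution* is 100 x (its sum of
positive voxel weights) / (total positive weight mass), and regions are
ranked 1, 2, 3, ... by descending contribution within the fold (ties to the
lower label).  Reported per region: fold-mean contribution, fold-mean rank
(the *expected ranking*, ER), and the fold-mean of the region's mean voxel
weight (which preserves sign information that the contribution discards).
Negative weights are excluded from contributions deliberately — the
displayed convention for such weight maps shows positively-weighted voxels
only — which is also why the designated recovery test in the phantom has a
positive effect direction.  The published ER convention is ambiguous
(printed ERs below 1 for regions that rank first in every fold cannot be a
1-based fold-mean); ranks are 1-based here by default with a `rank_base=0`
switch, and ER values should be compared only within a convention.

## 6. Association statistics

Partial Pearson correlations (score vs. age or lesion volume, controlling
for sex as a 0/1 indicator and education in years) residualize both
variables on `[1, covariates]` by least squares; r is the residual Pearson
correlation and the two-sided p comes from `t = r sqrt((n-2-q)/(1-r^2))`.
A variable numerically fully explained by the covariates reports r = 0,
p = 1 rather than failing.  The diffusion analysis computes, per subject,
the mean FA/MD/AD/RD over the top-5 contributing regions and fits one OLS
per (test, metric) pair — score on the 5 region means — reporting the
overall F and its p-value ("multivariate regression" in the
one-F-per-pair sense; a multi-response model would not produce that table).
An exactly collinear design raises; an exact fit reports F = inf with a
flag.  No correction across tests is applied, matching the analysis being
reproduced; regressions are unadjusted with an optional covariate argument.

## 7. Problem sizes and what the tests show

Default experiment sizes are chosen so the full pipeline runs in minutes on
one core: 12-subject cohorts for segmentation checks (10 training), 50
subjects for prediction and interpretation, 150–200 for demographic
associations, 99 permutations in scripted runs.  Passing tests demonstrate
that the algorithms are implemented correctly and that the pipeline
recovers structure it is designed to recover under its own generative
assumptions — clean intensities, pre-aligned single-space volumes, linear
score models.  They do not demonstrate clinical performance: real lesion
boundaries, registration error, scanner effects, and non-linear
brain–behaviour relationships are all outside the phantom.

## 8. Known limitations

* Single common space; no registration, bias-field, or skull-stripping.
* Phantom intensities are unrealistically separable; Dice near 1.0 on
  phantoms is a correctness check, not an expected clinical figure.
* The ER convention cannot reproduce sub-1 printed ERs (see section 5).
* Kernel RVR carries the sample-space limits described in section 3.
* `sigma^2` is floored at `1e-12 var(y)` and posterior factorizations are
  jittered on failure (logged); both matter only on degenerate inputs.
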