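# Methods

`rficlass` re-implements, as a tested pipeline over synthetic data, a
two-step strategy for classifying animals into high/low residual-feed-intake
(RFI) classes from bulk RNA-Seq counts: filter-style gene ranking by
conditional permutation importance in a subsampling forest, followed by
classifier comparison (SVM, random forest, elastic net, nearest shrunken
centroids) under nested stratified cross-validation.

## Residual feed intake

RFI is defined per animal as the residual of daily feed intake (FI, kg/day)
regressed within sex on metabolic body weight (MBW = BW^0.75, kg^0.75),
average daily gain (ADG, kg/day) and backfat gain (BFG, mm over the test
period):

    FI_ij = S_j + b_MBW,j MBW_i + b_ADG,j ADG_i + b_BFG,j BFG_i + RFI_ij

with sex j. The two within-sex ordinary-least-squares fits are
mathematically identical to one model with sex-specific intercepts and
sex-by-covariate interactions, and residuals are exactly orthogonal to the
covariates within sex — a property the tests assert at 1e-8 after scaling.
The feeding protocol is deliberately NOT a regression term: it had no effect
on RFI in the motivating experiment, so it enters only (a) the sex-by-
protocol cells used when selecting phenotypic extremes and (b) the factors
screened during batch detection. Class contrasts use a `RFI ~ class * sex`
linear model; least-squares means coincide with cell means because the model
is saturated in those two factors. Extreme selection labels, within each
sex-by-protocol cell, the k lowest-RFI animals `low`, the k highest `high`,
and a k-wide block centered on the cell median `mid`; ties are broken by
animal id, so selection is a deterministic partition.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes rather than any
particular data set: 65 animals in a 32/33 split (16/16 females/males in the
high class, 17 low-class males), four feeding protocols cycling within
sex-by-class cells, and negative-binomial counts.

* **Counts.** Gene baseline abundances are log-normal (log2 means drawn
  N(3, 1.8^2)); per-sample library sizes are mean-corrected log-normal
  around `mean_lib_size` (default 10^6, sigma = 0.2); counts are
  Gamma-Poisson with a single dispersion (default 0.1, a typical bulk
  RNA-Seq value). Signal genes (default 50) are shifted +/- `signal_logfc`/2
  (default 1.5 log2 units) per class with random sign.
* **Batch.** A single continuous latent factor, correlated with sex at
  `sex_batch_corr` (default 0.9), loads with a common magnitude and random
  sign on a random half of the genes. The loading is calibrated
  analytically — batch variance = f/(1-f) times the delta-method noise
  variance of log2(count+0.5) summed over genes — so that the leading
  principal component of the log-normalized matrix explains about
  `batch_variance_frac` (default 0.3) of total variance. The tests verify
  0.3 +/- 0.1 across seeds.
* **Phenotypes.** BW ~ N(105, 7) kg (MBW = BW^0.75), ADG ~ N(0.95, 0.07)
  kg/day, BFG ~ N(6, 1.5) mm, sex intercepts -0.85/-1.0 kg/day and
  coefficients (0.08, 0.7, 0.01) — values chosen once to give realistic
  grower-finisher feed intakes near 2.4 kg/day. FI adds
  `class_effect_on_fi` (default 0.45 kg/day, between the two printed
  sex-specific class gaps of 0.56 and 0.31) times the centered class
  indicator, plus N(0, 0.15) noise; with that noise the class gap is
  2.8-3 SD units of RFI, matching the 1.9-3.5 SD context of the selection
  experiment. Residualizing FI on covariates attenuates the recovered gap
  by the projection of the class indicator on the fitted subspace
  (about 3/(n_sex - 1), roughly 9%); the test suite computes this
  attenuation exactly per replicate instead of ignoring it.

What the generator does NOT emulate: gene-gene co-expression beyond the
batch axis, gene-length or GC effects, outlier samples, litter/pen structure
and multiple tissues. Passing tests therefore demonstrate correctness of the
machinery and its behaviour under the planted model, not performance on real
tissue data — in particular the planted signal (50 genes at log2FC 1.5 with
dispersion 0.1) is far cleaner than real RFI biology, and classifiers reach
AUROC near 1 where the real study reported 0.85.

## Normalization and batch adjustment

Counts are filtered (gene total < 10 dropped) and converted to
log2(CPM + 0.5). Trimmed-mean-of-M-values scaling factors (30% M-trim, 5%
A-trim, inverse-asymptotic-variance weights, reference = library whose upper
quartile is closest to the mean upper quartile, factors normalized to unit
product) multiply the library sizes; the implementation is written here and
cross-checked in the tests both against an independent recoding and against
edgeR's `calcNormFactors` through Rscript. PCA uses the 500 most variable
genes, per-gene centering and no unit-variance scaling (the common default
for expression PCA; scaling is an open choice and is documented, not
configurable away silently). Components are screened against known factors
(Pearson for continuous covariates, one-way ANOVA R^2 for categorical;
constant covariates yield an `undefined` row, not an exception). Adjustment
regresses every gene (not only the PCA subset) on the selected component
scores with intercept and keeps the residuals; it is idempotent and leaves
each gene numerically orthogonal (< 1e-10) to the removed components. The
default adjusts PC1 only: adjusting PC2 as well brought no further
improvement in the motivating analysis, so `adjust_components=(1,)` with
both exposed in configuration.

## Gene ranking: conditional permutation importance

The ranking forest grows `n_trees` (default 1000) Gini CART trees, each on a
without-replacement subsample (fraction 0.632 — the expected bootstrap
coverage, chosen because subsampling without replacement is what makes
permutation importances unbiased when predictors differ in scale) with
`mtry` candidate features per split. `mtry` is tuned over
{5, ..., floor(sqrt(p))} with step max(1, floor((sqrt(p)-5)/5)) by
out-of-bag accuracy on a 100-tree pilot forest, ties to the smaller value.
Single trees come from scikit-learn; the subsampling scheme, OOB
bookkeeping and the importance measure are implemented here. Full
conditional-inference (permutation-test-based) splitting is intentionally
not replicated; the two ingredients that matter for the ranking —
subsampling without replacement and conditional permutation — are.

Importance of gene g is the mean over trees of the OOB accuracy drop when
g's values are permuted **within strata**: for each tree, the conditioning
set is the set of predictors used in that tree whose absolute Pearson
correlation with g exceeds 0.2 (the published default of the conditional-
importance method), and the strata are the cells of the partition induced by
that tree's own split thresholds on those predictors. An empty conditioning
set degrades gracefully to an unconditional permutation. Trees that never
split on g contribute a drop of exactly 0 (permuting an unused variable
cannot change predictions), which the implementation exploits for speed.
One random permutation per gene and tree is used by default (`n_permutations`
raises it); an `exact=True` mode enumerates every within-stratum permutation
for verification on tiny cases and is compared against brute-force
enumeration in the tests. Ranking ties are broken by gene id.

## Classifiers

All four learners share one contract: `fit(X, y, params, seed) -> model`,
`model.scores(X') ->` class-1 probabilities, where class 1 is **high RFI**
(the positive class; low RFI, the more efficient animals, is negative).
Features are standardized inside each learner from training data only. RF
and SVM fits sort training rows canonically first, so every learner is
exactly invariant to sample order.

* **Elastic net** (binomial deviance). The penalty follows the convention
  in which alpha weights the RIDGE term:
  `lam * ((1-alpha) * sum|b| + alpha * sum b^2)`, alpha = 0 is the lasso,
  alpha = 1 ridge, tuned over {0, 0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85,
  1}. For each alpha a descending lambda path (30 values by default, down to
  0.01 of the smallest all-zero lambda) is cross-validated on the inner
  folds by binomial deviance and the one-standard-error rule picks the most
  regularized lambda within one SE of the minimum; alpha is then chosen by
  the cross-validated AUROC at its selected lambda. Path fits use an
  accelerated proximal-gradient (FISTA) solver with adaptive restart,
  glmnet-style sequential strong-rule screening plus a KKT check, and a
  dual-space solver for pure ridge (the optimum lies in the row space of X);
  soft-thresholding produces exact zeros, which is what the vote accounting
  counts. The solver is cross-checked in the tests against scikit-learn's
  saga on the identical objective and against ridge/lasso closed forms on
  orthonormal designs; lambda = 0 falls back to an unpenalized logistic fit.
  Coefficients are reported on the standardized-predictor scale.
* **SVM.** RBF kernel, C and gamma on power-of-two grids with integer
  exponents -12..12 (25 x 25 combinations by default). Tuning ranks
  combinations by decision-value AUROC (monotone-equivalent and much
  cheaper); final fits calibrate probabilities by Platt-style sigmoid
  scaling on internal CV folds. Calibration is required to be monotone in
  the decision values: with near-constant decisions the fitted sigmoid
  slope can flip sign numerically, in which case the raw decision ordering
  is used instead. Note libsvm's slack penalty is per data point, so the
  duplication invariance of the decision function pairs "duplicate every
  point" with "halve C".
* **Random forest.** Bootstrap ensemble of Gini trees (500 by default),
  probability = vote fraction; `max_features` is the tunable.
* **Nearest shrunken centroids.** Offsets
  d_ik = (xbar_ik - xbar_i) / (m_k * scale_k * (s_i + s0)) with
  m_k = sqrt(1/n_k - 1/n) (the variance of a class-vs-overall mean
  difference), pooled within-class SD s_i, stabilizer s0 = median(s_i) by
  default, and a per-class `threshold_scale` multiplying the (s_i + s0)
  term — the reading adopted for the terse "class-dependent scaling factor
  for the within-class standard deviation". Offsets are soft-thresholded by
  delta (tuned on a relative grid, delta as a fraction of max|d|, so one
  grid serves any data scale) and centroids rebuilt; prediction minimizes
  the standardized squared distance minus 2 log prior, ties to the
  larger-prior class; probabilities are the softmax of -delta_k/2. Genes
  shrunk to zero in both classes leave the rule entirely, giving the
  built-in gene selection the vote accounting uses.

## Nested resampling and gene-importance aggregation

The outer loop is stratified 10-fold cross-validation (per-class fold counts
differ by at most 1; folds are deterministic given the plan seed, which fans
out from the global seed via `numpy.random.SeedSequence` spawn keys).
Hyperparameters are tuned for each outer-training set by an inner stratified
10-fold loop on that set only; the model is refit on the full outer-training
set at the tuned values and scored on the untouched outer-validation fold
(AUROC by the rank/concordance formulation with ties counted 1/2; accuracy,
sensitivity and specificity at probability threshold 0.5 — AUROC is
threshold-free, and 0.5 is the natural choice for calibrated
probabilities). The repetition count is a plan parameter (1, 5 or 50),
never hard-coded. A leakage audit in the tests corrupts outer-validation
labels under fixed folds and verifies no tuned hyperparameter moves.

Gene **votes** count, per gene, the fitted models with that gene selected
(nonzero elastic-net coefficient, or surviving shrunken-centroid offset);
following the published accounting the counted fits are the inner-fold fits
at the tuned hyperparameters, so the ceiling is repetitions x outer_folds x
inner_folds (500 for 5 x 10 x 10). A stricter outer-refits-only count
(ceiling repetitions x outer_folds) is emitted alongside for transparency.
**sumbetas** accumulates the signed standardized-scale coefficients over the
same fits. Learners without a selection notion (SVM, RF) simply contribute
no votes.

Feature-ranking placement is configurable: the pipeline driver defaults to
re-ranking inside each outer-training set (leakage-safe; rankings are
computed once per outer fold and shared across learners and subset sizes),
while `rank_scope="global"` ranks once on the full cohort, which is how
the two-step procedure was originally described. The analysis drivers and
the acceptance script use the global mode.

## Problem sizes and numerical choices

Desk-scale study conditions are 65 samples x 2,000 genes with 50 planted
signal genes — large enough for the 500-most-variable-gene PCA and the
p >> n regime, small enough to run a full pipeline in minutes. The
end-to-end suites use: 10 outer x 5 inner folds, one repetition; elastic-net
alpha grids of 3-5 values with 12-point lambda paths; a 7 x 7 power-of-two
SVM grid (exponent step 4); 300-500 ranking trees with mtry fixed at
floor(sqrt(p)) where the mtry sweep itself is not under test; batch-benefit
cohorts of 1,000 genes with log2FC 0.8 so that classification is off the
AUROC ceiling and the effect of PC1 adjustment is visible. The full grids
(9 alphas, 25 x 25 SVM, 1,000 trees with the mtry sweep, 10 x 10 folds)
remain the defaults of the respective configuration objects.

Other numerics: FISTA tolerance 2e-5 (max 250 iterations) for tuning-path
fits and 1e-9 (max 5,000) for final fits; CPM prior count 0.5; PCA via SVD
with a deterministic sign convention (largest-magnitude loading positive);
all ties anywhere (gene ranking, extreme selection, grid search, class
assignment) broken deterministically as documented above.

## Known limitations

* The conditional-importance forest uses Gini splitting, not
  conditional-inference trees; importance values are therefore not
  bias-corrected for predictors with wildly different numbers of distinct
  values (irrelevant for all-continuous expression input, which is the use
  case).
* The elastic-net "internal CV" tunes lambda on the same inner folds that
  pick alpha (one inner level, jointly), rather than running a third nested
  loop per alpha; with the one-SE rule this matches standard
  `cv.glmnet`-inside-tuner usage at a fraction of the cost.
* Synthetic cohorts have a single batch factor and independent genes given
  class and batch; real co-expression makes conditional importance both
  more necessary and harder.
* Binary classes only; `mid` animals are carried by the phenotype stages
  but not classified.
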