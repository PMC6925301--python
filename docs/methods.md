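# Methods

## Data model and the analytic yardstick

The simulator draws two classes from p-variate normal populations with a
shared covariance matrix: class 0 from `N_p(mu1, V)` and class 1 from
`N_p(mu1 + eps * 1_S, V)`, where `eps` is a common scalar mean shift
applied to the informative trait subset `S` (all traits by default) and
`mu1` defaults to the zero vector — only the mean difference matters under
a shared covariance.  Supported covariance families:

| family              | entry (i, j)             | constraint            |
|---------------------|--------------------------|-----------------------|
| `identity`          | `sigma^2 * 1[i=j]`       | —                     |
| `compound_symmetry` | `sigma^2 * rho^(1[i!=j])`| `-1/(p-1) < rho < 1`  |
| `ar1`               | `sigma^2 * rho^|i-j|`    | `|rho| < 1`           |
| `custom`            | caller-supplied          | symmetric positive definite |

Under equal priors the optimal classifier achieves `Phi(Delta/2)` with
`Delta^2 = (mu2-mu1)' V^{-1} (mu2-mu1)` (Mahalanobis separation).
`bayes_accuracy` evaluates this closed form and anchors the calibration
tests: a correct harness must place LDA's held-out accuracy at large n
within Monte-Carlo error of it, and any classifier at exactly 0.5 when
`eps = 0`.

`epsilon` may also be a grid `(start, stop, step)`; replicate generations
then consume the grid round-robin (or uniformly at random, by flag).  Both
readings of "averaging classification accuracy over a range of mean
shifts across repeated generations" are defensible; round-robin is the
default because it is deterministic.

### The canonical benchmark configuration

`canonical_run_config()` fixes n1 = n2 = 150, p = 25, compound symmetry
with sigma = 1, rho = 0.2, and eps = 2.25 on all traits.  That puts the
full-feature Bayes accuracy at 0.9902 and the top-3-trait Bayes accuracy
near 0.95, so rank-fraction sweeps are non-degenerate: accuracy must
climb visibly from the 10% column toward the all-features column.  With
rho > 0 every trait is informative but partially redundant, which is what
makes the 50%-vs-100% plateau meaningful.  The reference protocol is
10 repeats of stratified 10-fold CV; 100 repeats (the full-scale
protocol) is one config knob away but changes no conclusion, only the
standard errors.

### What the generator does and does not emulate

It reproduces the statistical skeleton of an image-derived trait table:
correlated numeric traits, balanced two-class labels, exchangeable
samples.  It does not emulate temporal structure across imaging days,
heteroscedastic or non-Gaussian trait distributions, zero-inflation from
segmentation failures (the preprocessing tests construct those defects
explicitly instead), or genotype-level clustering.  Tests passing on this
generator therefore validate the machinery — ranking, tuning hygiene,
fold bookkeeping — not the biology of any particular crop experiment.

## Preprocessing

Stages run in a fixed order: missing-value handling, outlier masking,
reproducibility, collinearity.  Every stage is a projection (idempotent)
and only removes or flags rows/columns/cells, never edits a value.

* **Missing values.** Image exports code empty measurements as 0, so zero
  cells in non-exempt trait columns count as missing alongside NaN.
  Policies: drop affected samples, drop traits whose missing fraction
  exceeds a cutoff (default 0.5), or mask cells as NaN.
* **Grubbs test** (default): `G = max|x_i - xbar| / s` against the
  two-sided critical value `((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2))`,
  `t = t_{1-alpha/(2N), N-2}`, applied per (replicate group x trait) and
  iterated (max 20 rounds) until nothing is flagged or fewer than 3
  points remain.  Equidistant extremes flag the lower sample index, for
  determinism.  Flagged cells become missing — the plant's other traits
  survive — and the missing-value policy is re-applied.
* **Bonferroni outlier test**: externally studentized residuals of the
  location-only model on N-2 degrees of freedom, two-sided p-values
  multiplied by N and capped at 1; flags where adjusted p < alpha.
* **Reproducibility**: Pearson correlation of paired replicate values per
  trait (all within-group pairs); traits with r below `r_min` are
  removed.  Fewer than 3 complete pairs, or degenerate pair variance,
  marks the trait "not assessable" (retained with a warning).  `r_min = 0`
  disables the filter.
* **Stepwise VIF**: `VIF_i = 1/(1 - R_i^2)` from regressing trait i on the
  other survivors plus an intercept; the largest VIF is removed (ties:
  lowest column index) while it exceeds `vif_max`, stopping once two
  traits remain.  Perfect collinearity and constant columns get VIF = inf
  and are removable, not numerical failures.  Exact VIFs need more
  complete samples than traits; otherwise the stage refuses and points to
  prior filtering.

Default thresholds — alpha = 0.05, `r_min` = 0.7, `vif_max` = 10 — are
conventional working values, all exposed in the config; none is canonical
for any particular dataset.

## SVM-RFE ranking

Each round trains a soft-margin linear SVM (cost C = 1 by default; tuning
C inside the elimination loop is deliberately out of scope) on the
surviving traits and scores trait i by `R_i = w_i^2` — the leading
second-order term of the change in the SVM objective when the trait is
dropped.  The lowest-scoring trait is eliminated and prepended to the
ranking; with `step_size > 1` the same number of lowest-scoring traits
leave per round, reverting to single eliminations near the end so the
full permutation is always produced.  The final survivor takes rank 1
without a degenerate one-trait training round.

Numerical choices:

* Traits are z-scored (training statistics) before ranking by default;
  `w_i` has units 1/unit(x_i), so unscaled criteria are not comparable
  across heterogeneous image traits.  With standardization the ranking is
  invariant to per-trait affine rescaling.
* The SVM solver tolerance is 1e-8, and squared weights below 1e-10 are
  snapped to exact zero before the argmin.  An inseparable surviving set
  has w = 0 exactly; what a solver returns there is noise at the 1e-7
  level, and without the snap the elimination order among such traits
  would depend on the solver rather than on the documented
  lowest-column-index tie-break.  The brute-force QP oracle in the test
  suite applies the same rule, and the 200-instance equivalence check
  passes exactly.
* Multi-class labels are rejected; every experiment here is binary.

## Classifiers

All four methods sit behind one `ClassifierSpec` -> fit -> predict
contract with name-based column alignment.

* **LDA** — pooled-covariance linear discriminant with equal priors; no
  tuning.  The default SVD solver degrades exactly as classical LDA does
  when p approaches the per-fold sample count, which is the honest
  behavior for high-p regimes; an optional ridge (`lda_ridge`, default
  off) stabilizes the pooled covariance when singularity is a problem
  rather than a finding.
* **Random forest** — `n_trees` = 500, `mtry` (features tried per split)
  defaulting to all selected traits.  CART-style trees with bootstrap
  aggregation; the contract is ensemble-vote accuracy, and no claim of
  equivalence to other forest flavors (e.g. conditional-inference trees)
  is made.
* **SVM-l / SVM-r** — soft-margin SVMs with per-fold z-scoring inside the
  model pipeline.  Grids: `C in {2^0..2^4}`, and for the RBF kernel
  additionally `gamma in {2^-8..2^0}` (45 settings).  Tuning is 5-fold
  stratified CV on the training partition only; exact ties resolve toward
  smaller C, then smaller gamma.

## Cross-validation harness

Stratified k-fold (default k = 10) repeated `repeats` times with
independently seeded shuffles; fold partitions are exact and per-fold
class proportions sit within one sample of the global proportions.
Accuracy aggregates as mean over folds within repeat, then mean and SE
(std/sqrt(repeats)) over repeat means.  Note that repeat means share one
dataset, so this SE captures partition-resampling variance; the
Monte-Carlo error of a cell mean is better estimated from the dispersion
of all fold accuracies, which is what the trend tests use.

`rank_inside_fold` (default) recomputes the ranking on each training fold
before selection, tuning and fitting, so held-out rows never touch any
training statistic — verified by a leakage audit in which a
label-revealing trait injected into held-out rows only leaves accuracy at
chance while the same trait injected everywhere drives it to ~1.0.
`rank_once` evaluates an externally fixed subset and exists to reproduce
the optimistic protocol in which ranking precedes cross-validation;
the package does not claim either protocol as anyone's actual procedure.

Because a fold's ranking depends only on its training rows, sweep cells
share one ranking cache per (repeat, fold).  Per-cell runtime therefore
reports tune+fit+predict seconds, with ranking time accounted separately;
folding the shared ranking cost into each cell would make the
all-features column (which never ranks) look artificially cheap.

### Known limitation: runtime ordering at desk scale

At the canonical scale (n = 270 training rows, p <= 25) per-cell
wall-clock is only coarsely increasing in the rank fraction: libsvm
iteration counts *fall* as the selected subset becomes more separable,
sub-second LDA cells are jitter-dominated, and random-forest time can
even decrease with more informative features because trees get shallower.
The expectation "more surviving features, more wall-clock" therefore does
not hold cell-by-cell at this scale, and the test suite's runtime-ordering
check documents that honestly by failing: the runtime profile is computed
and reported per cell, but no monotone ordering of these wall-clock
numbers should be relied upon below the problem sizes where per-feature
cost dominates.

## Reproducibility

One global seed expands into per-module and per-(repeat, fold) seeds via
`SeedSequence` hashing of integer/string paths (`phenoselect.seeds`); no
module reads global random state.  Identical config + seed reproduces
every artifact byte-for-byte, including the accuracy TSV; run directories
carry the config hash and derived seeds needed to re-run themselves.

## Scope limits

Non-Gaussian generators, unequal class covariances, multi-class labels,
nonlinear-kernel RFE, PCA-based selection, probability calibration and
parallel execution are out of scope.  Real trait tables enter as generic
CSV (samples x numeric traits with label/metadata columns); no
image-processing or dataset-specific logic is included.
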