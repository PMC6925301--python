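# phenoselect

Filtering, SVM-RFE ranking and cross-validated benchmarking of
image-derived plant phenotype trait tables.

High-throughput phenotyping platforms convert daily plant images into
tables of hundreds of numeric traits (projected area, height, color and
fluorescence summaries, ...) per plant and day.  Before those tables can
train a stress/non-stress classifier they need cleaning — image exports
code missing measurements as `0`, replicated plants carry gross outliers,
and many traits are near-duplicates — and the surviving traits need to be
ranked so the classifier can use the informative few instead of all of
them.  `phenoselect` implements that two-phase workflow for plant
scientists and anyone benchmarking feature selection on tabular
biological data:

1. **Processing** — zero/NaN missing-value handling, Grubbs or Bonferroni
   outlier tests per replicate group, trait-reproducibility filtering by
   Pearson correlation of replicate pairs, and stepwise removal of
   collinear traits by variance inflation factor (VIF).
2. **Ranking** — SVM-RFE: a soft-margin linear SVM is trained on the
   surviving traits, each trait is scored by its squared weight
   `w_i^2` (with `w = sum_t alpha_t y_t x_t` over support vectors), the
   lowest-scoring trait is eliminated, and the loop repeats until every
   trait has a rank.
3. **Evaluation** — repeated stratified k-fold cross-validation of LDA,
   random forest, and linear/RBF SVMs (with their standard 2-power
   hyperparameter grids) on the top 10%…50% and 100% of the ranking,
   yielding a methods x rank-fraction accuracy table.

A two-class multivariate-normal simulator with a closed-form optimum
accompanies the pipeline: two p-variate Gaussian populations share a
covariance matrix `V` and differ by a common mean shift `eps` on an
informative trait subset, so the best achievable (Bayes) accuracy is
`Phi(Delta/2)` with `Delta^2 = (mu2-mu1)' V^{-1} (mu2-mu1)` — an analytic
yardstick for every classifier and for the harness itself.

## Worked example

```python
from phenoselect import (
    ClassifierSpec, CVProtocol, SimulationConfig, bayes_accuracy,
    fraction_sweep, simulate_two_class, svm_rfe,
)

config = SimulationConfig(
    n1=150, n2=150, p=25, epsilon=2.25,
    cov_family="compound_symmetry", sigma=1.0, rho=0.2, seed=1,
)
table = simulate_two_class(config)
print(round(bayes_accuracy(config), 4))      # 0.9902

ranking = svm_rfe(table, C=1.0)
print(ranking.ranked_traits[:3])             # ['trait_023', 'trait_006', 'trait_015']

grid = fraction_sweep(
    table,
    [ClassifierSpec("lda"), ClassifierSpec("svm_l")],
    fractions=[0.1, 0.2, 0.3, 0.4, 0.5, 1.0],
    protocol=CVProtocol(k=10, repeats=10, seed=1),
)
print(grid.to_frame().round(2))
```

which prints the mean CV accuracy (%) per method and rank fraction:

```
         10%    20%    30%    40%    50%   100%
lda    93.87  96.93  98.40  98.07  98.03  97.70
svm_l  93.93  96.70  98.03  98.00  97.90  98.03
```

Reading: with only the top 10% of ranked traits (3 of 25) both
classifiers already reach ~94%, and from 30% onward they plateau within a
fraction of a point of the all-features column — half of the ranking
carries essentially all usable signal, close to the 99.02% Bayes limit of
this generator.  Every trait here receives the same shift, so the
plateau reflects diminishing returns of correlated traits, not dead
features.

The same experiment runs from the shell:

```bash
phenoselect sweep --config configs/canonical.yaml --out-dir runs/canonical
phenoselect report runs/canonical
```

Short narrative scripts, one per capability, live in `examples/`.

## Two ranking protocols

`CVProtocol(rank_mode="rank_inside_fold")` (default) reruns SVM-RFE on
every training fold, so held-out rows never influence trait selection,
hyperparameter tuning or standardization statistics.  `rank_once`
evaluates a fixed, externally chosen subset instead; ranking on the full
table before cross-validation leaks test information and inflates
accuracy, and the package implements it only so both protocols can be
compared.

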