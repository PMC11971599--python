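# Methods

## The prediction problem

An ordinal response takes one of `k` ordered categories (school grades,
rating-scale answers, severity grades) coded `1..k`. Regression forests can
be used for ordinal prediction by assigning numeric scores to the categories,
training on the scores, and translating numeric predictions back to
categories through a partition of the score axis by borders
`b_1 <= ... <= b_{k+1}` (a prediction in the r-th subinterval is labelled
`r`). The two free choices in this framework are the scores and the borders.
Methods that optimize the scores (and take the borders as interval midpoints)
pay a large computational price for situational benefit; the method
implemented here keeps the default scores `1..k` and instead adapts the
*borders*, cheaply, from information the forest produces anyway.

## Frequency-adjusted borders

`fit_fabof` trains one regression forest on the integer scores and collects
the averaged out-of-bag (OOB) prediction `ŷ_i` of every training row — the
average over only those trees whose bootstrap sample excluded row `i`. With
`π_r = #{y_i <= r} / n` the cumulative relative category frequencies of the
training response, the interior borders are the empirical OOB-prediction
quantiles

    b_{r+1} = q_{π_r}(ŷ_1, ..., ŷ_n),  r = 1..k-1,

and the bounding borders are fixed at `b_1 = 1`, `b_{k+1} = k`, the extreme
values a leaf mean of integer scores can take. By construction, mapping the
OOB predictions through these borders reproduces the training category
distribution up to quantile discreteness; the same approximately holds for
test data drawn from the same population. The implicit assumption — and the
method's main sensitivity — is that the training category distribution
represents the population one predicts for. Using OOB rather than in-sample
predictions mimics calibration on unseen data without a held-out set.

Prediction is aggregate-first-transform-after (AFTA): tree-level numeric
predictions for a new row are averaged first and the average is mapped
through the borders once. The vote-based alternative (TFAA), in which each
tree's prediction is first categorized and the categories are majority-voted,
is provided for the naive-ordinal-forest baseline; vote ties break toward
the lowest tied category so results are reproducible (the choice is a local
convention — any fixed rule would do).

### Numerical conventions

* **Intervals** are half-open `[b_r, b_{r+1})` with the top interval closed.
  Values outside `[b_1, b_{k+1}]` clip to the extreme categories.
* **Quantiles** use linear interpolation between order statistics
  (`numpy.quantile` default, identical to R's type-7 default), fixed so that
  borders are reproducible across backends.
* **Empty categories** produce tied cumulative frequencies and hence
  duplicated borders; the empty interval is unreachable and fitting proceeds
  with a warning. A cumulative frequency of exactly 1 places its border at
  `k` rather than at `max(ŷ)`, so that predictions tied with the maximum OOB
  value do not spill into an empty upper category.
* **Rows in-bag in every tree** have no OOB prediction and are excluded from
  the quantile computation with a warning. At the default 500 trees the
  probability of such a row is `(1 − (1 − 1/n)^n)^500 ≈ 0.632^500`,
  i.e. never in practice.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `trees` | 500 | ensemble size; also drives OOB coverage |
| `covariates_per_split` | `max(1, floor(p/3))` | candidate covariates per split (regression-forest convention) |
| `min_node_size` | 5 | minimum observations per leaf |

Forest fitting is delegated to scikit-learn's `RandomForestRegressor`;
identical seed and data give bit-identical models, and a fitted model
serializes to a bundle that round-trips predictions exactly.

## Permutation variable importance

Because the numeric-to-ordinal transformation happens only after aggregation
across trees, a tree-level importance is not meaningful here; the permutation
cycle therefore runs at the forest level and is replicated `reps` times
(default 100) per covariate to stabilize the estimate. For covariate `j`,
replicate `m`: shuffle column `j` (fresh seeded permutation), recompute
forest predictions, and record the drop in linearly weighted kappa relative
to the unpermuted baseline. A covariate no tree splits on yields exactly zero
for every replicate. Two evaluation modes exist: `"oob"` (default) scores
OOB-style predictions on the training rows, mirroring how the borders are
calibrated and avoiding optimism; `"holdout"` scores full-forest predictions
on supplied data. Which data the importance cycle should use is genuinely
open; both are provided.

The implementation batches all replicates of one covariate into a single
leaf-lookup pass per tree, which keeps the `p × reps` forest re-predictions
tractable on one CPU.

## Baselines

* **naive OF** — same regression forest, fixed half-integer borders
  `0.5, 1.5, ..., k+0.5` (with AFTA prediction this is rounding the averaged
  score to the nearest integer, half-integers rounding up); TFAA or AFTA.
* **classification RF** — ordinality-ignoring forest, majority vote, ties to
  the lowest class.
* **RFSp** — `k−1` binary forests for the events `Y <= r`; cumulative
  probabilities are made monotone in `r` by a running maximum, differenced
  into category probabilities, and the modal category is returned. The
  monotonization/argmax rule is a documented local convention.
* **CLM** — proportional-odds cumulative-logit model with all linear main
  effects (statsmodels `OrderedModel`), labelled by the modal predicted
  category. Note statsmodels parameterizes `P(Y<=r) = F(θ_r − x'β)` whereas
  the simulator uses `P(Y<=r) = expit(γ_r + g(x))`, so recovered slopes are
  the negated generating coefficients.

Score-optimizing ordinal forests (random-partition search or non-linear
score optimization) are intentionally not implemented; the harness treats
any object with `fit(dataset, seed)`/`predict(X)` as a plug-in predictor.

## Metrics

Weighted kappa `κ_w = 1 − Σ v o / Σ v e` with disagreement weights
`v_ij = |i−j|/(k−1)` (linear) or its square (quadratic), observed proportions
`o` and chance-expected proportions `e` from the marginal product; Kendall's
`τ_b` (tie-corrected, appropriate for heavily tied ordinal data; delegated to
scipy and cross-checked against an enumeration oracle in the tests);
multiclass Youden `J` as the unweighted mean of one-vs-rest
`sensitivity + specificity − 1` (classes absent from the truth are skipped
with a warning; the unweighted mean is a documented choice).

## Synthetic data

The simulator emulates tabular psychology/epidemiology data: `p = 15`
uncorrelated standard-normal covariates, six influential (`X1..X6`), nine
noise. Four generating mechanisms:

1. proportional odds, `P(Y<=r|x) = expit(γ_r + g1(x))`;
2. numeric outcome `g1(x) + N(0, σ)` (default `σ = 1`) binned at calibrated
   cut-points — the common discretized-continuous-outcome use case;
3. proportional odds with the mixture predictor `0.6·g1 + 0.4·g2`;
4. DGP 1 with `X5`, `X15` replaced by Bernoulli(.5) covariates and the `X5`
   coefficient doubled from .5 to 1 to compensate the variance loss.

The shipped predictor coefficient sets are package defaults (configurable):

    g1(x) = 1.0·x1 + 0.75·x2 + 0.5·x3² + 1.0·sin(2·x4) + 0.5·x5 + 1.0·x6
    g2(x) = 0.5·x1 + 1.0·x2 + 1.0·x3 + 0.5·x4 + 1.0·x5 + 0.5·x6

`g1` mixes linear with smooth non-linear effects; `g2` is all-linear with a
different weight pattern. Thresholds `γ_r` (and DGP-2 cut-points) are
calibrated empirically: a pilot sample (default 100,000) of the latent value
`V = L − g(x)` (`L` standard logistic; for DGP 2 the numeric outcome itself)
is drawn and `γ_r` is its quantile at the cumulative target probability.
This pilot-quantile calibration is valid for arbitrary predictor
distributions, at the cost of Monte-Carlo error of order `1/√pilot_n` in the
achieved marginals. Two marginal patterns are supported: `equal` (each
category `1/k`) and `wide_middle` (defaults `(.10, .20, .40, .20, .10)` for
`k = 5`; a symmetric triangular profile for other `k`).

A study draws a pool of 10,000 observations, then an analysis sample of `n`:
training `2n/3` (category-stratified, or uniformly random to create a
train/population mismatch), test `n/3` (always stratified). What the
generator deliberately does *not* emulate: correlated covariates,
partial-proportional-odds effects, hierarchical/grouped structure, missing
data. Conclusions from passing tests are therefore about the calibration and
ranking behaviour of the methods under clean tabular conditions, not about
robustness to those complications.

## Study scales used in the test suite

The packaged end-to-end checks run scaled-down versions of the full studies
so the whole suite stays desk-sized: the border-calibration check uses 50
datasets of size 500 (500 trees); the fabOF vs naive-OF comparison uses 50
replications at `n = 750` with 100-tree forests; the importance-recovery
study uses 20 datasets of size 1000 (500 trees, 50 permutation replications).
Directional conclusions (which method wins, which covariates rank above
noise) are stable at these sizes; variance-sensitive quantities would need
the full replication counts.

## Known limitations

* Category probabilities are not available from fabOF (labels only), so
  probability-based measures (e.g. the ranked probability score) cannot be
  computed for it.
* The importance measure is an unconditional permutation scheme; with highly
  correlated covariates, importance can split across correlated partners and
  permutation creates unrealistic covariate combinations.
* Border calibration inherits the representativeness assumption: under
  non-stratified training sampling the borders track the (possibly
  distorted) training distribution.
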