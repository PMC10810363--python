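# replearn

**Repeated random-sampling evaluation of machine-learning methods, with
uncertainty quantification, leakage-safe feature screening and
resampling-weighted feature importance.**

## The problem

A single train/test split answers the wrong question. It scores *one* model
fitted on *one* random subset at *one* training-set size, and in biomedical
settings — where cohorts are small and features (genes, CpG sites,
metabolites) vastly outnumber samples — that estimate is unstable, usually
optimistic, and silent about how performance depends on how much data you
had. Two practices make it worse: screening features against the response
*before* splitting (the held-out data has then already leaked into the model),
and reporting a point estimate with no measure of its variability.

`replearn` evaluates the *methodology*, not one model: for each training-set
size in a grid, the data are repeatedly split at random into independent
training and held-out sets; screening and hyperparameter tuning see only the
training rows; and every repeat's held-out score feeds a per-size mean with a
confidence interval. The result is a learning curve with error bands, an
automatically selected best model, and feature-importance scores aggregated
over every model fitted along the way.

## The statistics

For training-set size *i* with *n* repeated splits, the per-split held-out
scores `performance_ij` give

```
M_i   = (1/n) Σ_j performance_ij                      (mean performance)
s_i²  = (1/(n−1)) Σ_j (performance_ij − M_i)²          (unbiased variance)
SEM_i = s_i / √n
CI_i  = M_i ± c · SEM_i
```

with `c` the Student-t quantile at the configured confidence level (default
95%, n−1 df). The overall best model is selected in two stages on the test
slice: first the size with the lowest CI upper bound (minimized metrics; the
highest lower bound for maximized ones), then the model with the optimal test
score at that size.

Hyperparameters are tuned per split by grid search on shared inner resamples
(default tenfold CV). Besides the optimal configuration, the
**one-standard-error** configuration is reported: the simplest configuration
whose mean inner score lies within one SE of the optimum.

Global feature importance is the performance-weighted mean over **all**
fitted models:

```
FIS_i = Σ_j w_j · importance_ij / Σ_j w_j
importance_ij = presence_ij · sign_ij · stability_ij
w_j = performance_j²            (maximized metric)
w_j = 1/(performance_j + ε)²    (minimized metric)
```

where `presence` is 0/1 feature membership, `sign` the coefficient sign
(where the learner has coefficients), and `stability` the fraction of inner
tuning fits that kept the feature.

Supervised screening inside each training split offers an empirical-Bayes
moderated t-test (per-feature variances shrunk toward a moment-matched
prior — stable when features outnumber samples) and/or a label-permutation
test. Unsupervised, response-blind filters (missingness, expression
threshold, SD/IQR/MAD variability) apply once, before any sampling.

## A worked example

```python
import replearn as rl

ds, truth = rl.simulate_regression(n_obs=200, n_features=50, n_informative=3,
                                   coefficient_scale=2.0, noise_sd=0.5, seed=1)
spec = rl.LearnerSpec("glm_penalized", "regression",
                      {"alpha": [0.01, 0.05, 0.1, 0.5], "l1_ratio": [1.0]})
grid = rl.SizeGrid(sizes=(20, 60, 160), n_repeats=10)
ev = rl.evaluate_method(ds, spec, grid, metric="mse", seed=1)
print(ev.summaries_frame().query("slice == 'test'")
        [["size", "mean", "sem", "ci_low", "ci_high"]])
```

prints (held-out MSE per training size):

```
 size     mean      sem   ci_low  ci_high
   20 0.986153 0.401065 0.078880 1.893425
   60 0.307557 0.011501 0.281539 0.333575
  160 0.255369 0.023296 0.202669 0.308069
```

With 20 training samples for 50 features the lasso is deep in the
high-dimensional regime — mean MSE near 1.0 and a CI spanning almost the
whole range. By 160 samples the error approaches the irreducible noise floor
(σ² = 0.25) and the interval tightens. `rl.select_best_model(ev, "mse")`
picks size 160 (lowest CI upper bound) and within it the repeat with the
smallest test MSE (0.1895 here). `rl.aggregate_importance(ev)` then ranks
the three planted predictors at FIS +1.0 / −1.0 / +1.0, matching their true
signs, with every noise feature well below.

The `examples/` directory holds one short script per capability (learning
curves, importance, screening, reports, external validation); each prints
what it computes and what the numbers mean. A thin CLI wraps the same
library: `replearn simulate | filter | evaluate | best-model | importance |
report | predict-external`.

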