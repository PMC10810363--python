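# Methods

This note documents the statistical machinery behind `replearn`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Evaluation model

The quantity estimated is the expected held-out performance of a *learning
methodology* (learner family + screening + tuning protocol) as a function of
training-set size. For each size `N_i` in a grid and each repeat
`j = 1..n`, the engine:

1. draws a random split of the observations into a training set of exactly
   `N_i` rows and its complement as the held-out set;
2. optionally screens features on the training rows only (supervised
   screening);
3. grid-searches the hyperparameters on inner resamples of the training set
   (default tenfold cross-validation), scoring every configuration on the
   *same* inner splits so configurations are compared pairwise;
4. refits the chosen configuration on the entire training split;
5. scores the refit model on the training rows, the held-out rows and the
   full data, for every requested metric.

`performance_ij` entering the per-size summaries is the held-out score of
the tuned-and-refit model (macro-averaged over classes for multiclass
metrics). Per size: mean `M_i`, unbiased SD `s_i`, `SEM_i = s_i/√n` and
`CI_i = M_i ± c·SEM_i`.

**Critical value.** `c` is the Student-t quantile with `n−1` degrees of
freedom at the configured confidence (default 95%). The sampling
distribution of a mean of a handful of resampled scores is unknown; t is the
conservative choice for small `n` and converges to the normal quantile as
`n` grows. Coverage is verified empirically in the acceptance checks
(95% ± 1% over 10,000 replicates at n ∈ {5, 20}).

Repeat scores at one size are positively correlated (they share
observations), so the nominal CI is approximate — standard for repeated
subsampling; the coverage simulation uses independent draws by construction.

**Best-model selection** is two-staged on the test slice: the size with the
lowest CI upper bound (minimized metrics) or highest lower bound (maximized),
then the record with the optimal test score at that size. Train/full
summaries are reported but never drive selection. Sizes with an undefined CI
(a single defined repeat) fall back to comparing means; ties prefer the
smaller size.

**Size grid.** The default grid runs from `⌈n/2⌉` to `n−1` in equal floor
steps, with the final element pinned at the maximum. Note the top of the
default grid leaves very few held-out samples; for variance-sensitive
metrics (MSE especially) a maximum that retains ≥ 20% of the data held out
gives a far more stable learning curve, and the recovery experiment in the
acceptance suite uses sizes (20, 60, 160) on n = 200 for exactly this
reason — it spans the high-dimensional regime (n_train < p) through
convergence while keeping ≥ 40 test samples per repeat.

## Resampling

Three schemes: subsampling without replacement (held-out = complement),
bootstrap (held-out = out-of-bag complement of the distinct drawn indices;
the expected unique fraction 1−(1−1/n)^n ≈ 0.632 is verified by simulation),
and k-fold cross-validation (folds differ by ≤ 1 in size and partition the
data exactly; k = n is leave-one-out and only honoured when requested
explicitly).

Stratification: *proportionate* allocation preserves strata fractions with
largest-remainder rounding (ties broken by stratum order, so every stratum
with a positive quota remainder is preferred in input order); *balanced*
allocation starts from `⌊size/#strata⌋` and hands the remainder to strata in
decreasing availability. Under balanced sampling without replacement a
stratum that cannot supply its share is an error, never a silent truncation.
Internally indices are 0-based; every serialized artefact is 1-based.

## Unsupervised filters

Applied once, before any sampling, and by construction blind to the
response (the functions do not accept one):

- **missing ratio** — keep a feature iff its missing fraction ≤ cutoff;
- **threshold** — keep iff the value *strictly* exceeds the threshold
  (equality fails) in ≥ `min_samples` samples; the threshold is a constant
  or each sample's own median across features (the minimal-expression
  convention for transcriptomics); `min_samples` accepts an absolute count
  or a fraction (default 50% of samples);
- **variability** — keep the `⌈keep·p⌉` features with largest SD, IQR or
  MAD. MAD is scaled by 1.4826 (normal consistency; switchable). Ties and
  ranks break deterministically by feature order; missing values are ignored
  pairwise.

## Supervised screening

Run strictly inside each outer training split, between sampling and tuning.

**Moderated t.** Per-feature pooled two-sample variances `s_g²` (d residual
df) are modelled as scaled-F draws around a prior `s0²` with `d0` df. The
prior is estimated by moment matching on `log s_g²` (digamma/trigamma
matching, Newton trigamma-inverse). The statistic uses the posterior
variance `s̃² = (d0·s0² + d·s²)/(d0 + d)` and is referred to t with `d + d0`
df. Limits behave as expected: `d0 = 0` recovers the classical pooled t;
`d0 → ∞` tests every feature against the common prior variance. The
implementation is validated against Bioconductor limma on a fixture matrix
and by a null-calibration simulation. If every pooled variance is zero the
prior is inestimable and screening errors out. Features with zero standard
error report statistic 0.

**Permutation test.** Labels are permuted, features fixed; two-sided p via
the add-one estimator `(1 + #{|t_b| ≥ |t_obs|})/(B + 1)` (default B = 1000),
which can never return 0. In exhaustive mode all distinct label assignments
are enumerated and p is the exact fraction (the identity assignment
guarantees p > 0); the suite checks it against full enumeration.

**Selection rule.** p < α (default 0.05) capped at the `top_k` (default 500)
smallest p-values; `both` intersects the two tests' selections. Multiclass
responses are screened one-vs-rest with the minimum p per feature. An empty
selection falls back to the smallest p-values (default 1 feature) with a
warning, so fitting never receives an empty design.

## Learners and tuning

Five families (penalized GLM, random forest, linear SVM, gradient boosting,
kNN) delegate to scikit-learn behind one adapter that adds what the engine
needs: name-based feature alignment (a missing column is an error, never a
positional guess), per-feature presence/sign extraction (nonzero
coefficients for GLM/SVM; nonzero split importance with sign 0 for tree
ensembles; all-present with sign 0 for kNN, which uses every feature in the
distance), and a declared **complexity order** for the 1SE rule: larger
penalty is simpler (GLM), larger k (kNN), smaller C (SVM), fewer/shallower
trees (forest, boosting). The "generalized kNN" family is adapted as
standard kNN.

Grid search scores all configurations on identical inner splits; a
configuration's mean excludes undefined (NaN) scores, with the valid count
kept, and a configuration with no defined score is dropped with a warning.
The 1SE configuration is the simplest whose mean lies within one SE *of the
optimum* (the optimum's own SE — the convention of the practice this rule
comes from) on the favourable side. The model refit on the training split
uses the best configuration by default (`rule="one_se"` switches). Tuning
stability is the per-feature presence frequency across the *m* inner fits of
the selected configuration (tenfold inner CV ⇒ m = 10); counting across all
configurations would mix models that were never candidates.

## Feature importance

`FIS_i = Σ_j w_j·importance_ij / Σ_j w_j` over **every** non-failed model of
the evaluation (all sizes, all repeats), with
`importance_ij = presence_ij · sign_ij · stability_ij ∈ [−1, 1]` and weights
`performance²` (maximized) or `1/(performance + ε)²` (minimized, ε = 10⁻⁸
guarding zero error). Weights default to the primary metric on the test
slice (configurable). Failed fits and models with an undefined weighting
score contribute neither weight nor importance. Consequences worth knowing:
FIS is scale-invariant in the weights, a never-present feature has FIS
exactly 0, and sign-less learners (trees, kNN) have FIS 0 everywhere — for
those families the support and stability columns carry the signal.

## Reports

Static, self-contained HTML (inline SVG, no network assets), one report for
the methodology and one for a single model. Report generation never refits
or rescores: every number comes from the serialized evaluation, and
regenerating from `evaluation.json` reproduces the file byte-for-byte
(matplotlib's SVG id salt is pinned and timestamps suppressed). Alongside
each figure a plot-data JSON is emitted for anyone wanting interactive
rendering. The "summarised features" violin panel plots the first
principal-component score of the model's features per class. ROC appears
for binary classification when the learner exposes a continuous decision
value, else the panel is omitted with a notice.

## Determinism and parallelism

Each (size, repeat) task derives four substreams (split, screening, inner
resampling, estimator seed) from `SeedSequence(master_seed,
spawn_key=(size_index, repeat_index))`. Tasks are embarrassingly parallel
(joblib) and results are assembled in task order, so outputs are
byte-identical regardless of worker count — asserted in the suite by
comparing serialized artefacts from 1- and 4-worker runs. This derivation is
part of the package's compatibility surface.

## Synthetic data

`simulate_classification` plants a mean shift of `effect_size` SD units in
`n_informative` standard-Gaussian features; `simulate_regression` draws
y = Xβ + ε with alternating-sign coefficients (so sign recovery is
non-trivial) and Gaussian noise. Defaults (n = 200 observations, 50–100
features, 3–5 informative, effect size 2 SD, noise SD 0.5) put the problems
in the small-cohort, moderate-SNR regime the framework targets. What the
generators deliberately omit: correlated features, batch effects,
non-Gaussian marginals, missing values and label noise. Passing recovery
tests therefore show the pipeline's logic is sound — leakage-free screening
finds planted signal, FIS ranks it correctly, learning curves fall with
size — not that any given real dataset will behave as cleanly.

## Numerical details and edge cases

- Undefined scores (precision with no positive predictions, R² of a
  constant response, MAPE guarded by ε = 10⁻⁸) propagate as NaN, are
  excluded from means with the excluded count reported, and are never
  coerced to 0.
- Negative out-of-sample R² is allowed and participates in best-model
  selection unchanged.
- Proportionate rounding uses largest remainders; exact ties keep stratum
  input order.
- `summarize_size` of a single value reports the mean with NaN CI bounds
  and flags n = 1.
- The leakage guard is structural (screening/tuning callables receive only
  training rows) and additionally asserted at run time (train/held-out
  disjointness per record) and end-to-end (a feature equal to the held-out
  response, noise on training rows, is never selected and never improves
  held-out scores).

## Problem sizes in the checks

The acceptance computations run on one CPU in minutes: CI coverage with
10,000 replicates; recovery over 20 master seeds of a 3-size × 20-repeat
lasso evaluation (n = 200, p = 50); 20 paired leakage runs; a 2-size ×
3-repeat determinism comparison; 10,000 bootstrap draws. These sizes were
chosen as the smallest that make the stochastic pass criteria statistically
comfortable rather than borderline.
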