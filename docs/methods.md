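# Methods

This note documents the statistical procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make every run
reproducible.

## Data model

A dataset is an `n × p` numeric matrix with one integer class label in
`1..C` per row (`C = 4` by default: STEMI, NSTEMI, UA, Other) under a
schema that declares each feature's scale. Categorical (nominal/ordinal)
features enter all downstream arithmetic as their integer codes — no
one-hot expansion — matching how such registry extracts are coded in
practice. Continuous ("ratio") features are min-max rescaled to
`[-1, 1]`:

    x' = 2 (x − min) / (max − min) − 1

The extrema are taken from a fit sample. Two scopes are supported:
`split` (default) fits on the training part of each resampling split
only, so no test-range information leaks into training; `global` fits
once on the whole dataset, mirroring the common single-pass preprocessing
of registry studies. Values outside the fit range map outside `[-1, 1]`
(no clipping), keeping the transform strictly monotone. A constant
feature maps to 0 with a warning rather than erroring, which keeps tiny
fixtures usable. Missing values are rejected at read time; no imputation
is offered.

## Synthetic registry generator

The generator emulates the statistical shape of an ACS admission
registry: n = 809 patients by default, class probabilities
(0.2769, 0.1582, 0.5155, 0.0494), the full 40-feature schema, and a
planted informative subset — by default features 4 (BMI), 10 (chronic
lung disease), 27 (calcium-channel blockers), 30 (systolic blood
pressure), 31 (troponin I elevation), 36 (hemoglobin) and 40 (ECG ST-T
pattern). Informative ratio features get per-class Gaussian location
shifts with a common spread on the raw clinical scale; informative
categorical features get explicit per-class code distributions. All
other features are class-independent noise: uniform over codes
(categorical) or one common Gaussian baseline in plausible clinical
units (ratio). An exact-count mode assigns labels deterministically and
shuffles row order, for reproducing a fixed class table.

All draws come from a single seeded NumPy `default_rng` (PCG64) stream
in a fixed order — labels first, then features in schema order — so a
seed pins a dataset bit-for-bit across platforms.

Default effect sizes are a design choice, not an estimate of any cohort.
They were calibrated once, before the test suite was frozen, to two
goals: a tuned classifier reaches roughly 0.8 test accuracy at n ≈ 800,
and every planted feature carries enough signal that the wrapper search
can find it. Troponin and the ECG ST-T pattern dominate (together they
nearly determine the STEMI/NSTEMI/UA distinction, as in the clinical
decision rule); the remaining five are moderate.

What the generator deliberately does **not** emulate: correlations
between features given the class (features are conditionally
independent), measurement error structure, missingness, or temporal
drift. Passing recovery tests therefore show that the pipeline finds
planted conditional-dependence structure of this simple form; they do
not certify behavior under correlated clinical covariates.

## Classifiers

All eight learners share one contract: `fit(train, validation=None)` on
a `Dataset`, `predict(X)` returning labels in `1..C`. Stochastic
trainers take an explicit seed and are bit-for-bit reproducible.

* **GLM** — one binary GLM per class against one-hot targets, decision
  by argmax of fitted means. Four distribution/link pairs: normal
  (identity; plain least squares), Poisson (log), gamma (reciprocal),
  inverse Gaussian (inverse squared), the latter three by iteratively
  reweighted least squares. Because one-hot targets sit on the boundary
  of the non-identity links' domains, the mean is clamped to
  `[1e-6, 1 − 1e-6]` before link evaluation. Multi-class-by-one-vs-rest
  is a design choice (the alternative of regressing the integer label
  invites ordinal artifacts). Rank-deficient designs are rejected with
  the collinear columns named.
* **k-NN** — Euclidean distance on the coded/normalized features,
  plurality vote among the k nearest (default k = 7). Every tie is
  deterministic: vote ties go to the class with the smaller mean
  neighbor distance, then the lower class index; equal distances at the
  k-th neighbor are resolved by training-row order.
* **Naive Bayes** — empirical priors; Laplace-smoothed code frequencies
  (α = 1) for categorical features; per-class Gaussians with a variance
  floor (1e-9) for ratio features; argmax in log space. Codes never seen
  in training contribute nothing rather than −∞.
* **ID3** — recursive information-gain maximization (entropy in bits);
  categorical features split multiway over codes, continuous features at
  the best midpoint between sorted distinct values; leaves predict the
  local majority. An unseen code at prediction time falls through to the
  node majority. Stopping: pure node, fewer than `min_samples_split`
  (2), or `max_depth`.
* **Bagging-ID3** — B = 50 seeded bootstrap resamples of size n, one
  tree each, plurality vote with ties toward the lower label. B is
  configurable; an identity-resample hook reduces the ensemble to plain
  ID3 for testing.
* **MLP** — one hidden layer, logistic sigmoids on hidden and output
  layers, one-hot targets, squared-error loss, full-batch gradient
  descent with momentum (classic backpropagation; softmax/cross-entropy
  deliberately not used to stay with the classic formulation). Early
  stopping on validation mean-squared error with a patience window;
  weights at the best validation error are kept. The model-selection
  grid for the hidden-node count is 2–13.
* **RBF** — two-step hybrid: m = 7 centers by seeded Lloyd's k-means,
  each spread set to the mean nearest-other-center distance (a heuristic
  chosen because only "centers and spreads" are specified by the classic
  recipe), then ridge-regularized least squares (λ = 1e-8) from Gaussian
  activations to one-hot targets.
* **ANFIS** — first-order Sugeno system on a grid partition (2 Gaussian
  membership functions per input, `m^p` rules capped at 1024). Hybrid
  training alternates exact least squares for the consequents with one
  gradient step on the premise parameters per epoch, with
  validation-based early stopping. The system regresses the integer
  class label and decodes to the nearest label (ties to the lower
  label); as a single-output regression onto an ordinal encoding it is
  expected to trail the discriminative learners.

## Feature selection

Sequential backward elimination wrapped around k-NN. For every k in the
grid (odd 3–13 by default), start from the full feature set; each round
scores every leave-one-out candidate subset by mean test accuracy over
`reps` stratified 0.7/0.3 train/test splits and keeps the argmax; stop
at one feature. The selected model is the global accuracy argmax over
everything scored, with ties resolved toward the smaller subset, then
the smaller k, then the earlier round. The search uses the whole
dataset, so the winning wrapper accuracy is optimistically biased; the
unbiased estimate comes from the separate evaluation protocol.

Within one search the `reps` splits are derived from the master seed
and shared across candidates, rounds and k values. This paired design
makes candidate scores directly comparable and enables the fast
evaluator: per split, per-feature squared-distance matrices are
precomputed (float32), so a candidate's distance matrix is its parent's
minus one feature's contribution. Neighbor selection and voting in the
fast path replicate the k-NN classifier's tie-break rules exactly; a
numba-compiled insertion-selection kernel is used when numba is
available, with a pure-numpy implementation as the cross-checked
fallback.

## Validation protocol

Repeated random sub-sampling: per repetition a fresh random partition —
train/test 0.7/0.3 (two-way) or train/validation/test 0.6/0.2/0.2
(three-way) — with per-repetition seeds derived from the master seed via
`SeedSequence`. Splits are stratified by default (largest-remainder
apportionment of each class across parts), keeping the 4.9% "Other"
class represented; stratification can be disabled. The full study
protocol assigns each classifier its splitting mode and repetition
count: ANFIS 50 and MLP 100 three-way, RBF and bagged ID3 1000
three-way, ID3/GLM/k-NN/Naive Bayes 1000 two-way. Hyperparameter tuning
(`model_select`) sees only the train and validation parts, scores every
grid value on the same splits, and breaks ties toward the smaller
value; the test part is touched once, by the final evaluation.

## Performance metrics

The confusion matrix `CM` has rows = actual and columns = predicted.
Accuracy is trace over total. The APM divides each row by its row sum;
the CPM is the Bayes inversion of the APM under class priors (defaults:
the empirical priors of the full dataset). Under a matrix's own
empirical priors the CPM reduces algebraically to column-normalizing the
CM, which serves as the independent oracle in tests. Zero-support rows
or columns produce zeros plus a machine-readable flag, never NaN.
Across repetitions, matrices and accuracies aggregate element-wise as
mean and sample standard deviation (n − 1; a single run reports 0 with
a flag). Per-run CPMs are computed from each repetition's matrix and
then averaged (the alternative — one inversion of the averaged APM — is
available but differs and is not column-stochastic in general).
Rounding to two decimals happens only at report time.

## Problem sizes used by the shipped runs

The acceptance script and test suite scale the protocol down so a full
run takes minutes: selection uses reps = 20 on k ∈ {3, 7} at n = 809;
classifier evaluation uses 4–30 repetitions per kind (the full protocol
values above remain the configured defaults); the MLP is tuned over the
full 2–13 grid with 2 tuning repetitions. The recovery experiment
scores Jaccard overlap between the selected subset and the planted
7-feature set over 10 generator seeds.

## Known limitations

* Conditional independence given class in the generator (above).
* The wrapper search is greedy; it is oracle-checked against exhaustive
  subset evaluation only at small p, and like any backward elimination
  it can drop a feature whose value is conditional on another.
* GLM IRLS with one-hot targets and clamped means is a pragmatic
  classifier, not a calibrated probability model.
* ANFIS at the default grid partition is limited to modest input
  dimensionality (`2^p` rules); it errors with advice to pass a reduced
  feature subset when the rule cap is exceeded.
* No probability outputs: all metrics are label-based by design.
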