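# Methods

## Problem setting

The package targets binary outcome prediction from small, high-dimensional
clinical tables: on the order of 10²–10³ samples, tens of features mixing
integer-coded qualitative indicators with continuous measurements, and
near-balanced classes. Two failure modes dominate there: redundant or
uninformative features degrade distance- and tree-based classifiers, and any
single classifier leaves accuracy on the table relative to a well-chosen
ensemble. The two components address these in sequence.

## Wrapped feature selection (XGBIBS / BFGSBS)

### Importance metrics

A gradient-boosted tree ensemble is fit on the training partition and each
feature is scored over the set X of splits that use it: `weight = |X|`,
`gain` and `cover` the mean split gain/cover over X, `total_gain` and
`total_cover` the sums, where the gain of a split is

    ½ [ G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ) ] − γ

with (G, H) the child sums of first/second-order gradients. Two identities
hold by construction and are enforced in tests: `total_gain = gain × weight`
and `total_cover = cover × weight`. Note that the bound `gain ≥ −γ` holds
only at λ = 0 (Cauchy–Schwarz on the bracketed term); for λ > 0 the
regularized child terms can fall below the parent term, so no such bound is
asserted in the regularized case.

Two importance sources are implemented. The in-package `TreeEnsemble`
representation makes the formulas independently testable against a
brute-force split loop; the production path reads the five metrics directly
from the fitted XGBoost booster's importance report. Both must satisfy the
identities above.

### Search space and queues

Features the booster never used (`weight = 0`) have all five metrics equal to
zero and are excluded from the search space. The filter is on `weight`
because it is the one metric whose zero is unambiguous: a feature with
`weight = 0` was never split on, which forces the other four metrics to zero
as well. The survivors are ordered twice: queue I1 ascending by metric i1
(deletion order — least important first) and queue I2 descending by metric i2
(re-addition order — most important first). Ties break lexicographically by
feature name so queue order is platform-independent. The default pair is
(i1, i2) = (total_gain, cover); `enumerate_metric_pairs` tries all 20 ordered
pairs with i1 ≠ i2 and keeps the best by validation accuracy, then dimension
reduction, then pair name.

### The search

A buffer subset O starts at the full set of queue features, with the best
subset/accuracy initialized to the full set's evaluation. A cursor N walks
I1 once; each step is:

* **Stage 1 (backward deletion):** remove the N-th feature of I1 from O
  unconditionally — the buffer keeps the smaller subset even if accuracy
  drops. If that feature already left the buffer, or removing it would empty
  the buffer, the step only advances N. Each evaluation updates the
  best-so-far on strict improvement.
* **Stage 2 (floating re-addition):** traverse I2 once from the front; each
  feature absent from O is tentatively added and kept only if the evaluation
  strictly improves on the current buffer's evaluation (re-used, not
  recomputed). Kept additions that also beat the best-so-far update it.

The loop terminates when N has visited every I1 position; a config option
allows extra full sweeps but the default is one, reading the cursor semantics
as a single pass. Strict (>) improvement everywhere prevents cycling between
equal-accuracy subsets and biases the result toward smaller subsets; on equal
accuracy the earlier (smaller, post-deletion) subset is retained. The call
budget is bounded by |I1|·(|I2|+1)+1 evaluations, and the evaluator caches
per-subset results so repeated queries are consistent and cheap.

The evaluation function is wrapped classification accuracy: train the chosen
classifier on the training partition restricted to the subset, score on the
validation partition. Validation — not test — drives the search; k-fold
evaluation inside the search was considered and rejected as a default on cost
grounds. Learner hyperparameters default to the libraries' defaults with a
fixed seed and a single thread; tests and the acceptance script pass smaller
tree counts (30–50) purely as a problem-size choice, which does not affect
any structural guarantee (the no-degradation property holds for any
evaluator).

## Sel-Stacking fusion

### Label-Proba meta-features

For each sample, each base classifier contributes the pair (predicted label,
positive-class probability); with M samples and N classifiers the
meta-feature block is M × 2N, ordered (label₁, proba₁, …, label_N, proba_N).
Labels are always the 0.5 threshold of the probability, enforced in one place
(`predict_label_proba`) so the pair is internally consistent for every
learner. Only the positive-class probability is stored — the negative-class
probability is its complement and adds no information. Ablation input modes
`label` and `proba` (width N each) exist alongside the default `label_proba`
(width 2N).

Training-partition meta-features are built out-of-fold with stratified,
seeded K-fold (default K = 6): each base model is fit on K−1 folds and
predicts the held-out fold, so no row's meta-features derive from a model
that saw that row. Holdout (validation/test) meta-features come from base
models refit on the full training partition — a deterministic, standard
choice in preference to fold-model averaging.

### Combination search

Every non-empty subset of the candidate roster (2^N − 1 subsets) is scored:
the meta-classifier — a linear-kernel SVM with C = 1, chosen for its low
capacity on the small meta-feature space — is trained on the subset's OOF
columns against the training labels and scored by accuracy on the subset's
validation columns. The argmax is kept; ties break toward fewer members, then
lexicographic tag order. Rosters above 12 candidates are refused without an
explicit override, since the search is exponential. A combination whose meta
training fails is logged, recorded, and excluded from the argmax. The test
partition enters only after the combination is chosen, to score the final
refit meta-classifier.

Each base classifier inside the fusion carries its own selected feature
subset from the selection stage (per-classifier subsets, not a shared one).

## Data handling

* **Container:** features are a float matrix with unique column names and a
  per-column qualitative/quantitative tag; labels are strictly {0, 1}. CSV
  I/O goes through pandas; integer-valued columns load as qualitative.
* **Preprocessing:** rows with more than `max_missing_frac` (default 0.5)
  missing cells are dropped; remaining missing cells are imputed by column
  median (quantitative) or mode (qualitative); rows with any quantitative
  |z-score| above `outlier_sd` (default 5) are dropped. Outlier removal
  iterates to a fixed point — z-scores shift after removal, and iterating
  makes the operation idempotent on its own output, which is also the tested
  contract. These rules are conventional defaults, not reconstructions of any
  particular clinic's pipeline, and all are configurable.
* **Splitting:** train/validation/test sizes are floor(n·r_train/Σr),
  floor(n·r_val/Σr), remainder — at n = 2990 and 6:2:2 this realizes
  1794/598/598 exactly. Stratified splitting (default, seed 42) allocates
  per-class counts by largest remainder against the exact global sizes, so
  class proportions stay within one sample per class per partition while the
  global sizes remain exact.

## Synthetic generator

The generator emulates the structure of the motivating clinical tables with a
known ground truth. Defaults: 2990 samples; 8 informative, 10 redundant and
50 noise features (68 total, matching the motivating scale); 32 columns
discretized to 0/1 (mimicking disease flags); label balance 0.5; effect size
1.0 on the log-odds scale.

Informative features are standard normal latents; the label is Bernoulli with
logit `Z β + b`, coefficients of magnitude `effect_size` with alternating
sign, and intercept b bisected on the realized scores so the expected
positive fraction equals the requested balance (exact calibration rather than
a closed-form approximation, deterministic under the seed). Redundant
features are informative latents plus N(0, 0.5²) noise; noise features are
independent standard normals. A seeded subset of columns is median-thresholded
to 0/1 and tagged qualitative; the label is generated from the continuous
latents, so discretization attenuates but does not remove a feature's
association. The generating probabilities, latents, coefficients and
per-feature roles are carried in `provenance` for testing.

What the generator does **not** emulate: real covariance structure among
clinical measurements, informative missingness, label noise from diagnostic
error, and non-logistic outcome mechanisms. Tests passing on this generator
therefore demonstrate algorithmic correctness and the directional claims
(selection never degrades, noise features are preferentially discarded), not
clinical-grade accuracy figures.

## Problem sizes used by the test suite and acceptance script

The behavioural tests run the search on 240–1000-sample tables with 12–25
features and 30–50-tree learners; the noise-rejection study uses the planted
configuration 5 informative + 20 noise, effect size 1.5, n = 1000, 30
repetitions (10 in the acceptance script); the acceptance script's reduced
study uses 600 samples, 20 features and the full five-classifier roster.
These sizes were chosen so a full run stays in the tens of seconds on one
CPU while every code path is exercised end to end.

## Known limitations

* CatBoost is supported as a tag but not bundled; the default roster is the
  five classifiers above.
* The search is greedy within its queue order; it does not guarantee a
  globally optimal subset, only never-worse-than-full-set.
* The combination search is exhaustive by design and exponential in the
  roster size; it is capped at 12 candidates without an explicit override.
* Accuracy is the only selection criterion (with dimension reduction
  reported, not optimized); calibration and ranking metrics are out of scope.
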