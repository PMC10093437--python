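# Methods

## The error-consistency statistic

A trained classifier evaluated on held-out samples defines an *error set*
E: the identities of the samples it misclassified. For two error sets the
error consistency is the Jaccard index

    EC(E_i, E_j) = |E_i ∩ E_j| / |E_i ∪ E_j|,

a value in [0, 1]: 1 iff the two models fail on exactly the same non-empty
sample set, 0 iff their failures are disjoint. When both sets are empty
the ratio is 0/0 and EC is *undefined*; `ecvalidate` represents this as
NaN and carries it through every layer (pairwise matrix, summaries, CSV as
an empty field, JSON as null, reports as "NA"). The undefined case is a
legitimate, rare outcome — a pair of perfect models — not an error, so it
is reported rather than raised.

Error sets are sets of *sample ids*, not feature rows. Ids are assigned
once when a dataset is loaded or generated and survive shuffling, fold
assignment and down-sampling unchanged; the classifier adapters therefore
receive ids alongside features, which real estimators ignore and the mock
classifiers use to key their behaviour.

Over n error sets, only the n(n−1)/2 pairs with i < j are computed
(the EC matrix is symmetric with unit diagonal), in lexicographic (i, j)
order so the serialized matrix is reproducible. The summary reports the
mean (AEC) and standard deviation over the *defined* pairs; undefined
pairs are counted separately and a warning is logged whenever any occur.
The SD uses the sample (n−1) denominator — a documented, fixed choice;
with a single defined pair the SD itself is undefined. Up to a
configurable cap (2000 sets) the full pairwise matrix is materialised;
beyond it the same mean/SD are accumulated in row blocks of the boolean
membership matrix, keeping memory linear in n (the two routes agree to
machine precision and are tested against each other).

## Validation procedures

Both procedures repeat K-Fold cross-validation m times (defaults K = 5,
m = 500; m is set high for the statistical reliability of the summary) with
a fresh shuffled fold plan per repetition.

**Internal approach** (default): each repetition unites its K disjoint
fold-wise error sets into one *master error set* with support = all N
samples, giving n = m error sets. Because the folds partition the ids,
the union is disjoint and the pooled overall accuracy per repetition
satisfies OA = 1 − |E|/N bitwise — an invariant the tests assert.

**External approach**: the user supplies an independent validation set (or
a stratified fraction, default 0.2, is split off). Every fold-trained
model predicts the entire validation set, giving n = m·K error sets with
support = the validation ids. Two accuracy families are reported under
distinct names — the pooled fold-test OA per repetition, and each model's
validation-set accuracy — because they measure different things and
neither is privileged.

Folds are stratified by default. Stratification is a deliberate package
choice (small biomedical datasets easily produce empty-class folds
otherwise); `stratified=False` restores plain K-Fold, and a class with
fewer than K members under stratification is an input error naming the
class. Fold planning and splitting delegate to scikit-learn's
StratifiedKFold/KFold/train_test_split.

**Seeds.** Every random decision is derived from one master seed through
numpy `SeedSequence` spawn keys: repetition r uses `(master, r)`,
down-sampling draws `(master, 1|2, prop_index, draw)`, bootstrap windows
`(master, 3, window)`. Any single repetition or draw is re-runnable in
isolation from its recorded seed, and two runs with equal master seeds
produce byte-identical machine outputs (wall-clock time appears only in
the human-readable report for this reason).

**Classifier contract.** The engine consumes any object with
`fit(X, y, ids)` / `predict(X, ids)`. scikit-learn estimators are wrapped
and cloned before every fit so repetitions share no trained state;
hyperparameter tuning happens before the estimator enters the engine, not
per repetition. Four reference learners are available as presets
(`svm-rbf`, `rf-100`, `logreg`, `adaboost-dt`). Mocks with exactly
predictable error geometry make the statistic testable without learning:
the planted-error classifier (fixed error ids, training-independent — its
master error set is exactly the planted set, so AEC = 1) and the
random-error classifier (a fresh independent error subset per fit — the
independence baseline). The random mock's seed stream is intentionally
shared across clones: a fresh draw per fit *is* its contract.

## The independence baseline

With error rate p = k/N, two independently drawn error sets overlap like
random k-subsets: E|∩| = k²/N and E|∪| = 2k − k²/N, so the
ratio-of-expectations approximation gives E[EC] ≈ k/(2N − k) — 1/9 for
p = 0.2. Before the engine was built, this target and its tolerance were
validated by direct simulation oracles (`scratch/oracle_*.py`): for *pure*
independent k-subsets the exact pairwise expectation is
E[X/(2k − X)] with X ~ Hypergeometric(N, k, k) = 0.11336 at N = 100,
k = 20 (a Jensen bias of +0.0023 over 1/9), while the fold-wise mechanism
the engine actually uses (one fresh subset per fold-fit, master set =
union of per-fold intersections) has expectation 0.1111 ≈ 1/9 with a
Monte-Carlo SE of 0.0017 for the m = 200 AEC. The acceptance tolerance —
|AEC − 1/9| ≤ 0.005 = 3 SE — was frozen from that oracle, before any
engine run.

## Synthetic data

The generators produce the two consistency regimes with known geometry:

* **Boundary data** — two isotropic unit-variance Gaussian classes whose
  centroids sit `class_separation` apart along the first feature axis.
  For balanced classes the Bayes-optimal accuracy is Φ(separation/2), an
  analytic anchor the tests check empirically (oracle midplane rule on
  n = 5000, within 2 Monte-Carlo SEs). Errors of any sensible classifier
  concentrate near the midplane, so EC is high.
* **Label-noise data** — separable classes with a recorded fraction of
  labels flipped uniformly at random. Flipped ids are ground-truth
  metadata (never visible to classifiers); on well-separated data a
  margin learner's error sets cover most of them, which the tests assert
  on a fixed-seed fixture.

Defaults — 400 samples, 5 features, separation 2.0, balanced classes —
are the package's reference conditions: moderate overlap where a linear
margin learner (logistic regression) and a 100-tree random forest reach
overall accuracy within 2 percentage points of each other, yet differ
clearly in AEC (≈ 0.89 vs ≈ 0.75 at m = 12, K = 5). These conditions
were fixed once from an engine-free probe before the engine existed and
are asserted as a 10-trial comparison (linear AEC > forest AEC at matched
OA in ≥ 8 of 10 seeded trials). The mechanism is systematic: the forest's
bootstrap/feature randomisation moves its errors between repetitions,
while margin-based fits keep failing on the same boundary samples.

What the generators do *not* emulate: categorical or mixed-type features,
class-dependent covariances, missingness, or the marginal distributions of
any real clinical dataset. Passing tests therefore demonstrate the
*method's* correctness and its qualitative learner ordering on controlled
geometry, not performance claims about any particular application domain.

## Down-sampling curves and rolling correlations

Each proportion p in the grid (default {0.2, …, 1.0}) receives
`draws_per_proportion` (default 10) stratified without-replacement
subsamples of round(p·N) rows, and each draw one full internal validation
run with a reduced repetition count (default m = 50 per point; the
desk-scale experiments in the tests and acceptance script use m = 10 with
N = 200). At p = 1.0 the draw is the full dataset and exactly one draw is
made, so the point reproduces a plain validation run under its recorded
seed — an identity the tests assert. Points whose realized n cannot
support K folds are skipped with a warning. Note the OA of a point is
measured *on the subsample*, so at small proportions easy-by-chance draws
produce high-variance, occasionally optimistic values; the trend line, not
any single point, carries the signal.

Trends use Cleveland-style LOWESS (statsmodels implementation,
default span 0.6), fitted separately to OA and to the defined-AEC points
and evaluated on the common grid of observed proportions; undefined-AEC
points are gaps, never zeros. Local linear smoothing reproduces exactly
linear data to numerical precision — a property the tests use as an
oracle.

Rolling correlations sort the (percentage, metric) pairs and slide a
window of `window_size` points (defaults ≈ 5%, 10%, 20% of the pair
count); each window yields the Pearson correlation between percentage and
metric (Spearman optional) and a percentile bootstrap interval from
`n_boot` (default 500) resamples of the window's pairs. Windows — or
bootstrap resamples — with zero variance on either axis are undefined
(NaN) and excluded from the percentiles; a fully degenerate window gets a
NaN interval rather than a crash.

## Reports

The human report renders OA and AEC as percentage cells in the compact
`mean (SD)` style with integer means and one-decimal SDs —
`75 (0.6)/72 (2.5)` — matching the conventional presentation of such
results; an undefined AEC renders as `NA` with an explanatory note. Full
precision lives in the machine outputs (`summary.json`, `oa.csv`,
`error_sets.csv`, `pairwise_ec.csv`), and every report number is
recomputable from those CSVs alone, which a test verifies.

## Numerical and degenerate-input choices

* Pairwise EC is computed via a boolean membership matrix and one integer
  matrix product; union sizes come from |A| + |B| − |A∩B|. Exact in
  integer arithmetic up to the float division.
* Undefined values are NaN throughout; comparisons and summaries use
  explicit NaN handling, never accidental propagation.
* `ErrorSet` enforces members ⊆ support and non-empty support at
  construction.
* Degenerate validation splits (empty part, single class under
  stratification), sub-K classes, overlapping train/validation ids, empty
  validation sets, non-numeric feature columns and duplicate ids are all
  rejected as invalid input (CLI exit code 2); classifier failures carry
  repetition/fold context (exit code 3).
* Problem sizes in the test-bench (N = 100–400, m = 10–200, 10
  comparison trials) were chosen as the smallest scales at which the
  statistical assertions have comfortable margins under their frozen
  tolerances.

## Known limitations

* Multi-class data is supported, but EC itself is label-agnostic: an
  error is an error, whichever wrong class was predicted.
* No probabilistic or confidence-weighted error sets; no multi-label
  tasks; no regression.
* The external approach's two accuracy families are both reported;
  deciding which to headline is left to the user.
* LOWESS trends are descriptive; no formal sample-size recommendation or
  extrapolation beyond proportion 1.0 is attempted.
* The learner-ordering result (linear vs forest AEC) is a tendency on
  boundary-type geometry, not a theorem; datasets exist where the
  ordering reverses.
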