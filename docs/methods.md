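# Methods

## Problem setting

Animal-borne biologgers record short bursts ("segments") of tri-axial
acceleration at a fixed rate (typically 10 Hz per axis). When a segment is
time-matched to a direct field observation of what the animal was doing, it
can be labeled with a behavioral mode (Standing, Walking, Eating, Soaring,
Flapping, ...). The package treats each segment as one classification unit,
under the assumption that the animal is engaged in a single behavior for
the duration of the burst. A small labeled calibration set is used to train
and validate a classifier, which is then applied to the (much larger) body
of unlabeled recordings, and optionally projected onto a GPS track.

## Feature catalog

Each segment is reduced to a vector of summary statistics. Per axis
(samples s_1..s_n): mean; sample standard deviation (divisor n-1);
population skewness; population excess kurtosis; min; max; range;
dynamic body acceleration DBA = (1/n) Σ|s_i - mean|; mean absolute first
difference (1/(n-1)) Σ|s_{i+1} - s_i|; mean-crossings count; and the
25th/50th/75th percentiles (linear interpolation between order
statistics). Across axis pairs: Pearson correlation. For the whole
segment: ODBA = Σ_axes DBA_axis, the standard activity/energy-expenditure
proxy in this literature.

Numerical conventions, chosen where the definitions are genuinely open:

- The standard-deviation *feature* uses divisor n-1 (descriptive-statistics
  convention); the *normalizer* scale uses divisor n (z-score convention,
  matching `StandardScaler` semantics).
- Mean crossings count strict sign changes of (s_i - mean); a sample
  exactly at the mean contributes no crossing.
- Skewness/kurtosis use biased (population) formulas; a zero-variance axis
  returns 0 for both, with a log warning, rather than NaN.
- Pearson correlation involving a constant axis is undefined; it is
  reported as 0 (with a log warning) so downstream estimators always see
  finite features.
- Segments need at least 2 samples per axis (first differences and the
  n-1 divisor are otherwise undefined).

The catalog is an open registry (`register_statistic`), so additional
statistics can be added without touching the pipeline. Spectral features
and vector-magnitude statistics are deliberately out of scope.

## Normalization and leakage

Features are z-scored to zero mean and unit standard deviation. The
normalizer is fitted on training data only: during cross-validation it is
refitted inside every fold on the training part, and a trained model
bundle stores its own fitted normalizer and re-applies it at prediction
time. Constant (zero-scale) columns are flagged degenerate and map to 0.
Fitting the scaler on the full table before splitting would leak
validation information into training; the fold-internal refit avoids
that, at the cost of not being bit-identical to workflows that normalize
first and split afterwards.

## Classifier families

Seven families share one train/predict contract: artificial neural
network (multi-layer perceptron), decision tree, linear discriminant
analysis, linear SVM, k-nearest neighbors, random forest, and RBF-kernel
SVM; quadratic discriminant analysis is available as an optional extra.
All are scikit-learn estimators. Hyperparameter defaults are era-typical
library defaults, recorded explicitly so results are reproducible:

| family  | defaults |
|---------|----------|
| ann     | one hidden layer of 10 logistic units, max 500 epochs |
| tree    | unlimited depth, Gini impurity |
| lda     | singular-value solver |
| linsvm  | C = 1, one-vs-rest |
| knn     | k = 5 |
| rf      | 100 trees |
| rbfsvm  | C = 1, gamma = 1/n_features |

All are overridable per `ModelSpec`. Stochastic families are seeded and
bit-reproducible. Label vocabularies are sorted, and kNN distance ties
resolve toward the lowest class index in that sorted vocabulary (the
underlying argmax convention). A trained bundle persists as a single zip
archive holding a JSON manifest (family, hyperparameters, seed, feature
names, vocabulary, normalizer parameters, format version) plus the
serialized estimator, so saved models are auditable without unpickling.

## Cross-validation and metrics

Three schemes: k-fold, train-split (k = 2, the default), and
leave-one-out, implemented literally as k-fold with k = n so the
equivalence holds by construction. Folds are stratified by default —
with class imbalance like 3.5% of a few hundred segments, unstratified
folds can starve a class — and degrade to plain k-fold with a warning
when some class has fewer members than k (always the case for
leave-one-out).

Per-behavior metrics use the one-vs-rest convention: accuracy_b =
(TP_b + TN_b)/N, precision_b = TP_b/(TP_b + FP_b), recall_b =
TP_b/(TP_b + FN_b). Zero-denominator metrics are undefined (NaN), shown
as an em dash in rendered tables and excluded from macro averages, never
reported as 0. The confusion matrix and per-behavior metrics are computed
on predictions pooled over all validation folds; the mean and standard
deviation of accuracy are computed across per-fold accuracies (sample
std, divisor k-1). Both views are reported because neither is canonical.
The model-comparison table reports accuracy and fold-std in percent with
an arithmetic-mean summary row, and accepts either freshly computed
reports or transcribed (accuracy, std) pairs, e.g. from a published
table.

## Bulk labeling and trajectory annotation

`label_file` appends a predicted-behavior column to a CSV. The file is
parsed up front (so format errors surface before any output is written)
and featurized/predicted in chunks of at most 100,000 rows by default, a
batching bound kept from the tool this workflow descends from; since
prediction is row-independent, output is invariant to the chunk size.
Input rows are preserved byte-for-byte. For raw inputs the bundle's
feature columns are recomputed from the file, with the needed axis count
inferred from the feature names; headerless stats files adopt the
bundle's feature names when the column count matches.

`stratified_subsample` caps each class at a fixed number of rows
(uniform, without replacement, seeded) to reduce over-dominance of common
behaviors in calibration sets; classes at or below the cap are kept
whole, so no class is dropped.

Trajectory annotation classifies timestamped ACC bursts and assigns each
GPS fix the behavior of the nearest-in-time burst within a tolerance
(default 10 s; exact ties go to the earlier burst); fixes with no burst
within tolerance are labeled "unknown". Output is a GeoJSON
FeatureCollection of Point features with a deterministic per-behavior
color drawn from a colorblind-safe palette by sorted behavior name, so
identical inputs produce byte-identical files.

## Synthetic data generator

Each behavior is generated as gravity + motion + noise per axis:

    s_a(t) = m·p_a + A_a·g(t)·sin(2π f t + φ) + ε,  ε ~ N(0, σ²)

with unit posture vector p, static magnitude m (nominally 1 g), per-axis
amplitude A, dominant frequency f (< Nyquist), phase φ (fixed or drawn
per segment), and noise σ. Intermittent behaviors use a square-wave
amplitude gate g(t) with a burst frequency and duty cycle. Default
segments are 4 s at 10 Hz (40 samples/axis), in the range typical of
burst-mode loggers.

Two built-in scenarios:

- **vulture-like** — six behaviors at the class mix of a field
  calibration set for a large soaring bird: Lying down 3.5%, Standing
  43.6%, Walking 13.7%, Eating 22.3%, Soaring 6.6%, Flapping 10.2%
  (the published percentages sum to 99.9% due to rounding and are
  renormalized), default n = 488. Signatures partially overlap, as in
  real data.
- **separable** — the same six behavior names in equal proportions,
  default n = 600. Five classes are strongly separated; Standing and
  Soaring are deliberately similar (both near-static and upright, noise
  0.10 g) so that classifier families differ measurably in accuracy
  while all remain above 90% — the scenario is built for end-to-end
  verification that the pipeline learns what is learnable, not for
  realism.

Class counts follow largest-remainder rounding (with a floor of one
segment per class); segment order is shuffled deterministically under the
scenario seed.

What the generator does *not* emulate: calibration error and per-tag
offsets, sensor saturation, within-segment behavior transitions,
broadband/biomechanical spectra (wingbeat harmonics), autocorrelated
noise, and duration variability. Passing tests on synthetic scenarios
therefore demonstrate pipeline correctness — feature math, fold
construction, metric arithmetic, persistence, chunking — not field-data
accuracy; published per-model accuracies on real calibration data are
not reproducible without that data.

## Problem sizes in tests

Unit tests run the pipeline at n = 90 segments; the end-to-end
evaluation checks use n = 600 with 10-fold stratified CV, and the
permutation-null check uses shuffled-label kNN at the same size. The
acceptance script (`scripts/acceptance.py`) uses 5 permutation
replicates; the test suite uses 20.

## Known limitations

- Raw-CSV rows must be uniform in width; variable-duration segments in
  one file are rejected (consistent with the row-oriented format this
  tool inherits), though the in-memory API accepts them.
- Header auto-detection assumes data rows are fully numeric outside the
  label/timestamp columns; exotic numeric-looking headers need the
  explicit `--header` override.
- Leave-one-out with stratification always degrades to unstratified
  folds (with a warning); this is inherent to singleton validation sets.
- GeoJSON output stores timestamps as numeric seconds, not ISO strings.
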