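# Methods

## Scope and model

The package implements ten k-nearest-neighbour classifiers behind one
contract — construct, `fit(train)`, `predict(queries)` — plus the
benchmark protocol used to compare such variants on binary
disease-prediction tables: accuracy/precision/recall from a
confusion matrix on a chosen positive class, best-k selection over the
grid {1, 3, 5, 7, 9}, per-dataset win counting, the Relative
Performance Index (RPI), and a one-way ANOVA treating variants as
groups and their per-dataset values as observations.

All neighbour searches are exact brute-force scans with distances
computed in double precision. This is a deliberate design boundary: the
intended datasets are at most a few hundred rows, where an index
structure buys nothing and an exact scan makes determinism trivial.

## Determinism and tie-breaking

Every source of order-dependence is pinned:

- Neighbour sorting is stable; equal distances resolve by training-row
  index.
- Vote ties go to the tied class whose closest member is nearest the
  query, then to the smallest class id (smallest value under the sorted
  order of the observed labels). The rationale: local evidence
  (a nearer supporter) should beat arbitrary enumeration order, and the
  rule is total, so every prediction is well defined.
- Best-k ties prefer the smallest k; candidate-k ranking ties in the
  locally adaptive variant likewise.
- All randomness (splits, the synthetic generator, k-means
  initialisation in `random` mode) flows through explicit integer seeds
  via `numpy.random.default_rng`.

Under these rules, fitting twice with the same configuration and seeds
is bit-identical, and permuting training rows cannot change any
prediction when all pairwise distances are distinct (the property the
test suite asserts).

## Variant-specific decisions

**Adaptive.** Each training point stores the smallest candidate k whose
leave-one-out vote classifies it correctly. When no candidate works,
the largest candidate is stored: the least local, most conservative
choice within the bounded search range. Candidates above n−1 are
dropped.

**Locally adaptive.** The published description of this variant — a
ranking table of candidate k values against centroid distances — leaves
the exact ranking formula open. The implemented rule scores candidate k
by the ratio of the query's distance to the centroid of the
majority-class neighbours over its distance to the centroid of the
second-majority ("discrimination") class neighbours, 0 for a
single-class neighbourhood, smallest ratio wins. This is a documented
stand-in for the original ranking formulae, chosen because it preserves
the construct the variant is named for (majority vs second-majority
contrast) and is total and deterministic. One consequence worth knowing:
a k = 1 neighbourhood is always single-class, so whenever 1 is among the
candidates the rule reduces to 1-NN.

**Fuzzy.** Crisp neighbour labels (each training point fully in its own
class) with weights 1/d^(2/(m−1)); Keller-style soft labelling of the
training set is out of scope. The fuzzifier defaults to m = 2 — the
standard choice, making weights inverse squared distances. A query at
zero distance from a training point gets membership 1 in that point's
class (nearest such point under the stable order if several coincide).

**K-means.** Our own Lloyd's loop (max 300 iterations, relative
centroid-shift tolerance 1e-4, empty clusters dropped, centroid labels
by majority with ties to the smallest class id). Default cluster count
round(√n_train). Three initialisations: `spread` (default) takes evenly
spaced rows of the lexicographically sorted feature matrix — fully
deterministic and invariant to row order, which keeps the
permutation-invariance guarantee that seeded random initialisation
cannot give; `random` draws training rows with a seed; `points` copies
the first n_clusters rows verbatim, so with n_clusters = n_train the
training set is a fixed point of Lloyd's algorithm and the classifier
is exactly 1-NN (the reduction law used in tests).

**Weight adjusted.** Inverse-distance kernel 1/(d + 1e-9); the epsilon
bounds the weight of an exact match at 1e9, which dominates any finite
competitor without producing infinities. The Gaussian kernel sets its
bandwidth per query to the mean neighbour distance, reducing to equal
weights when all neighbours are equidistant.

**Hassanat.** The metric sums per-dimension terms
1 − (1 + min)/(1 + max), with both arguments shifted by |min| when the
minimum is negative. Each term lies in [0, 1), so the metric is bounded
by the dimensionality and insensitive to per-feature scale — the reason
it needs no feature normalisation. The variant is classic voting with
this metric forced.

**Generalised mean distance.** The "iterative local mean" construction
is realised as nested cumulative means: for each class, the k nearest
members sorted ascending give local mean vectors m_j = mean of the
first j members, and the class score is the generalised mean with
exponent p of the distances d(q, m_j) (p = 1, the arithmetic mean, by
default; p = 0 the geometric mean; p < 0 with any zero distance takes
the limiting score 0). Any faithful reading of the construction
collapses to 1-NN at k = 1, which is the invariant tested.

**Mutual.** Mutuality is computed on the full training set (x and y
mutual iff each is in the other's k-NN list); isolated points are
pruned. At prediction, a surviving neighbour x votes only if
d(q, x) ≤ the distance from x to its k-th nearest surviving point —
i.e. the query would make it into x's own neighbour list. If the filter
removes all k neighbours the classic vote over those k neighbours is
the fallback, so a prediction always exists.

**Ensemble.** Kmax = round(√n_train), forced odd by subtracting 1,
minimum 1. Rounds k = 1, 3, …, Kmax each add 1/log2(r+1) for rank r;
since the rounds only extend one another, the per-rank weights are
pre-aggregated at fit time and prediction is a single weighted count.

All variants accept multiclass labels; nothing in any of the algorithms
is binary-specific. Precision/recall for more than two classes use
one-vs-rest macro averaging, an extension beyond the binary benchmark.

## Benchmark protocol

The train/test protocol of the original comparison is not recoverable,
so the package defaults to a single stratified holdout with
test fraction 0.3 and seed 42, all configurable. Preprocessing defaults
to median imputation (mode for categoricals, which are integer-encoded)
plus min-max scaling to [0, 1], both switchable off — a conventional
choice for mixed-scale clinical tables, made explicitly rather than
pretending to match an unknown original pipeline. For the same reason
the per-cell values of the original result tables are declared out of
reproduction scope; every summary statistic computable *from* those
printed tables (averages, win counts, RPI, ANOVA) is reproduced
exactly, via the same `summarize_tables` pipeline a fresh benchmark
uses.

Best-k selection is per measure (each measure keeps its own optimal k),
with per-accuracy selection (precision and recall read off at the
accuracy-optimal k) available as `GridSpec(best_k_by="accuracy")`; the
original text is ambiguous between the two. k-independent variants
(kmeans, ensemble) are fitted once per dataset, not once per grid point.

Undefined precision or recall (empty denominator) propagates as NaN
with a warning and is excluded from best-k maximisation; it is never
silently replaced by 0 or 1.

The ANOVA computes the sums of squares directly (between:
group-mean deviations times group size; within: residuals) and takes p
from the F distribution; `scipy.stats.f_oneway` serves as an
independent cross-check in the tests only. Zero within-group variance
with non-zero between-group variance reports F = ∞, p = 0.

## Synthetic data

`generate_synthetic` draws two isotropic Gaussian classes in d
dimensions with means `class_sep · noise_sd` apart per dimension and a
fixed class-1 count round(n · class_balance). Defaults (n = 400, d = 8,
noise_sd = 1, balance 0.5) mirror the size and width of the mid-sized
disease tables the benchmark targets; `class_sep = 2` gives the
realistic overlapping-classes regime. What it emulates: numeric,
moderately correlated-free tabular data with a binary outcome. What it
does not: categorical features, missing values, class imbalance beyond
the balance parameter, feature-scale heterogeneity, label noise, or
non-Gaussian class shapes. Tests passing on these mixtures therefore
demonstrate algorithmic correctness and determinism, not clinical
performance.

The test suite and the acceptance script run the full benchmark at
10 variants × 3 mixtures of 150 rows × the five-point k grid, and the
separability check at n = 400 — sizes at which the whole suite
completes in seconds while still exercising every code path at
realistic dimensionality.

## Known limitations

- The locally adaptive and generalised-mean variants implement
  documented interpretations of loosely specified constructions; other
  faithful readings exist and could rank candidate k values or pool
  local-mean distances differently.
- The published precision win-count column cannot be reconciled with
  counting column maxima of the published precision table (ties
  included); the package reproduces the accuracy and recall win counts
  and documents the discrepancy rather than guessing the original
  counting rule. Similarly, the published recall-average text value
  76.84 disagrees with the printed table average 76.80; the embedded
  fixture carries the table.
- Brute-force scans are quadratic in n; the package is not intended for
  datasets beyond a few thousand rows.
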