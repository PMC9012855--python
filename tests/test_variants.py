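"""Per-variant behaviour: hand-worked examples, reduction laws, oracle
agreement with brute force / scikit-learn, and determinism."""

import numpy as np
import pytest

from knnvariants import Dataset, VariantConfig, generate_synthetic, make_variant
from knnvariants.distances import get_metric
from knnvariants.variants import (
    VARIANT_NAMES,
    AdaptiveKNN,
    ClassicKNN,
    EnsembleKNN,
    FuzzyKNN,
    GeneralisedMeanDistanceKNN,
    HassanatKNN,
    KMeansKNN,
    LocallyAdaptiveKNN,
    MutualKNN,
    WeightAdjustedKNN,
)

ALL_NAMES = set(VARIANT_NAMES)


def brute_force_knn(X, y, q, k, metric="euclidean"):
    """Independent oracle: full distance scan + counting, stable ties."""
    fn = get_metric(metric)
    d = np.array([fn(q, x) for x in X])
    order = np.argsort(d, kind="stable")[:k]
    labels, dists = y[order], d[order]
    values, counts = np.unique(labels, return_counts=True)
    tied = values[counts == counts.max()]
    best = min(
        tied, key=lambda c: (dists[labels == c].min(), np.argmax(values == c))
    )
    return best


# ---------------------------------------------------------------------------
# classic

def test_classic_majority_three_neighbours():
    X = np.array([[0.0], [0.2], [0.4], [5.0]])
    y = np.array([1, 1, 0, 0])
    assert ClassicKNN(k=3).fit(X, y).predict([[0.1]])[0] == 1


def test_classic_k1_returns_exact_match_label(tiny_1d):
    X, y = tiny_1d
    m = ClassicKNN(k=1).fit(X, y)
    assert m.predict([[10.0]])[0] == "B"


def test_classic_full_enumeration(tiny_1d):
    X, y = tiny_1d
    assert ClassicKNN(k=5).fit(X, y).predict([[2.5]])[0] == "B"


def test_classic_k_too_large_rejected(tiny_1d):
    X, y = tiny_1d
    with pytest.raises(ValueError, match="k=7"):
        ClassicKNN(k=7).fit(X, y)


@pytest.mark.parametrize("metric", ["euclidean", "manhattan", "hassanat"])
def test_classic_matches_brute_force_oracle(metric, rng):
    """200 random (train, query, k) instances per metric."""
    for _ in range(200):
        n = int(rng.integers(5, 25))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 3, size=n)
        y[:2] = [0, 1]  # guarantee two classes
        q = rng.normal(size=d)
        k = int(rng.choice([1, 3, 5]))
        if k > n:
            k = 1
        model = ClassicKNN(k=k, metric=metric).fit(X, y)
        assert model.predict([q])[0] == brute_force_knn(X, y, q, k, metric)


def test_classic_matches_sklearn_on_distinct_distances(rng):
    """Cross-check against scikit-learn where no distance ties exist and
    the majority is unique (both implementations then agree exactly)."""
    sklearn = pytest.importorskip("sklearn.neighbors")
    X = rng.normal(size=(40, 3))
    y = rng.integers(0, 2, size=40)
    Q = rng.normal(size=(25, 3))
    for k in (1, 3, 5):
        ours = ClassicKNN(k=k).fit(X, y).predict(Q)
        ref = sklearn.KNeighborsClassifier(n_neighbors=k).fit(X, y).predict(Q)
        assert np.array_equal(ours, ref)


# ---------------------------------------------------------------------------
# adaptive

def test_adaptive_all_k1_reduces_to_1nn(blobs):
    """When every point's nearest neighbour shares its label, all stored
    k are 1 and prediction equals 1-NN."""
    m = AdaptiveKNN(k_candidates=(1, 3, 5)).fit(blobs)
    assert np.all(m.point_k_ == 1)
    Q = blobs.features + 0.01
    nn = ClassicKNN(k=1).fit(blobs)
    assert np.array_equal(m.predict(Q), nn.predict(Q))


def test_adaptive_fallback_is_largest_candidate():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array(["A", "B", "A", "A"])
    m = AdaptiveKNN(k_candidates=(1, 3)).fit(X, y)
    assert m.point_k_[1] == 3  # no candidate classifies the B point


def test_adaptive_inherits_nearest_points_k():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array(["A", "B", "A", "A"])
    m = AdaptiveKNN(k_candidates=(1, 3)).fit(X, y)
    # query next to point 3 (stored k=1) behaves like 1-NN
    assert m.point_k_[3] == 1
    assert m.predict([[3.1]])[0] == "A"


# ---------------------------------------------------------------------------
# locally adaptive

def test_la_single_class_neighbourhood_short_circuits():
    X = np.array([[0.0], [0.1], [5.0], [5.1], [5.2]])
    y = np.array(["A", "A", "B", "B", "B"])
    m = LocallyAdaptiveKNN(k_candidates=(1, 3)).fit(X, y)
    assert m.predict([[0.05]])[0] == "A"


def test_la_equal_ratio_prefers_smaller_k(blobs):
    """On pure blobs every candidate gives ratio 0; prediction must be
    deterministic and equal to the smallest-k majority."""
    m = LocallyAdaptiveKNN(k_candidates=(1, 3, 5)).fit(blobs)
    nn = ClassicKNN(k=1).fit(blobs)
    Q = blobs.features
    assert np.array_equal(m.predict(Q), nn.predict(Q))


# ---------------------------------------------------------------------------
# fuzzy

def test_fuzzy_known_memberships():
    X = np.array([[0.0], [3.0]])
    y = np.array(["A", "B"])
    m = FuzzyKNN(k=2, fuzzy_m=2.0).fit(X, y)
    mem = m.predict_memberships([[1.0]])[0]  # d = 1 and 2, w = 1, 1/4
    np.testing.assert_allclose(mem, [0.8, 0.2])
    assert m.predict([[1.0]])[0] == "A"


def test_fuzzy_single_class_neighbourhood_membership_one(blobs):
    m = FuzzyKNN(k=3).fit(blobs)
    q = blobs.features[blobs.labels == 0][0] + 0.001
    mem = m.predict_memberships([q])[0]
    assert mem.max() == pytest.approx(1.0, abs=1e-9)


def test_fuzzy_zero_distance_gives_crisp_membership(tiny_1d):
    X, y = tiny_1d
    m = FuzzyKNN(k=3).fit(X, y)
    mem = m.predict_memberships([[10.0]])[0]
    b_col = int(np.flatnonzero(m.classes_ == "B")[0])
    assert mem[b_col] == 1.0
    assert m.predict([[10.0]])[0] == "B"


def test_fuzzy_memberships_sum_to_one(overlap, rng):
    m = FuzzyKNN(k=5).fit(overlap)
    Q = rng.normal(size=(30, overlap.n_features))
    mem = m.predict_memberships(Q)
    np.testing.assert_allclose(mem.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(mem >= 0) and np.all(mem <= 1)


def test_fuzzy_rejects_bad_m():
    with pytest.raises(ValueError, match="fuzzy_m"):
        FuzzyKNN(k=3, fuzzy_m=1.0)


# ---------------------------------------------------------------------------
# k-means

def test_kmeans_point_init_full_clusters_is_1nn(blobs):
    m = KMeansKNN(n_clusters=blobs.n_samples, init="points").fit(blobs)
    nn = ClassicKNN(k=1).fit(blobs)
    Q = blobs.features + 0.01
    assert np.array_equal(m.predict(Q), nn.predict(Q))


def test_kmeans_hand_clusters():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array(["A", "A", "B", "B"])
    m = KMeansKNN(n_clusters=2).fit(X, y)
    np.testing.assert_allclose(sorted(m.centroids_.ravel()), [0.5, 10.5])
    assert m.predict([[3.0]])[0] == "A"


def test_kmeans_deterministic(overlap):
    a = KMeansKNN(n_clusters=5, seed=3, init="random").fit(overlap)
    b = KMeansKNN(n_clusters=5, seed=3, init="random").fit(overlap)
    Q = overlap.features
    assert np.array_equal(a.predict(Q), b.predict(Q))


def test_kmeans_too_many_clusters_rejected(blobs):
    with pytest.raises(ValueError, match="n_clusters"):
        KMeansKNN(n_clusters=blobs.n_samples + 1).fit(blobs)


# ---------------------------------------------------------------------------
# weight adjusted

def test_weight_adjusted_overrides_unweighted_majority():
    X = np.array([[0.0], [3.0], [4.0]])
    y = np.array(["A", "B", "B"])
    m = WeightAdjustedKNN(k=3, kernel="inverse_distance").fit(X, y)
    # neighbour distances 1, 2, 3: A gets 1.0, B gets 0.5 + 0.333
    assert m.predict([[1.0]])[0] == "A"
    assert ClassicKNN(k=3).fit(X, y).predict([[1.0]])[0] == "B"


def test_weight_adjusted_equidistant_reduces_to_majority():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    y = np.array(["B", "B", "A"])
    for kernel in ("inverse_distance", "gaussian"):
        m = WeightAdjustedKNN(k=3, kernel=kernel).fit(X, y)
        assert m.predict([[0.0, 0.0]])[0] == "B"


def test_weight_adjusted_exact_match_dominates(tiny_1d):
    X, y = tiny_1d
    m = WeightAdjustedKNN(k=3).fit(X, y)
    assert m.predict([[1.0]])[0] == "A"


# ---------------------------------------------------------------------------
# hassanat

def test_hassanat_metric_is_forced():
    assert HassanatKNN(k=1).metric == "hassanat"


def test_hassanat_nearest_under_hassanat_distance():
    X = np.array([[0.0], [1.0]])
    y = np.array(["A", "B"])
    # d(0.2, 0) = 1 - 1/1.2 ~ 0.167 < d(0.2, 1) = 1 - 1.2/2 = 0.4
    assert HassanatKNN(k=1).fit(X, y).predict([[0.2]])[0] == "A"


def test_hassanat_agrees_with_classic_when_orderings_agree(blobs):
    h = HassanatKNN(k=3).fit(blobs)
    c = ClassicKNN(k=3).fit(blobs)
    Q = blobs.features + 0.01
    assert np.array_equal(h.predict(Q), c.predict(Q))


# ---------------------------------------------------------------------------
# generalised mean distance

@pytest.mark.parametrize("exponent", [1.0, 2.0, -1.0, 0.0])
def test_gmd_k1_reduces_to_1nn(overlap, exponent):
    m = GeneralisedMeanDistanceKNN(k=1, gmd_exponent=exponent).fit(overlap)
    nn = ClassicKNN(k=1).fit(overlap)
    rng = np.random.default_rng(5)
    Q = rng.normal(size=(25, overlap.n_features))
    assert np.array_equal(m.predict(Q), nn.predict(Q))


def test_gmd_hand_local_means():
    X = np.array([[0.0], [4.0], [1.0], [5.0]])
    y = np.array(["A", "A", "B", "B"])
    m = GeneralisedMeanDistanceKNN(k=2, gmd_exponent=1.0).fit(X, y)
    # A local means {0, 2} -> score 1; B local means {1, 3} -> score 2
    assert m.predict([[0.0]])[0] == "A"


def test_gmd_identical_point_sets_tie_to_smallest_class():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([1, 0, 0, 1])  # both classes occupy the same positions
    m = GeneralisedMeanDistanceKNN(k=2).fit(X, y)
    assert m.predict([[0.5]])[0] == 0


# ---------------------------------------------------------------------------
# mutual

def test_mutual_prunes_isolated_point():
    X = np.array([[0.0], [0.1], [100.0]])
    y = np.array(["A", "A", "B"])
    m = MutualKNN(k=1).fit(X, y)
    assert len(m.pruned_X_) == 2
    assert set(m.pruned_y_) == {"A"}
    assert m.predict([[99.0]])[0] == "A"


def test_mutual_tight_cluster_equals_classic(rng):
    """With k = n-1 every point is mutual with every other, so nothing is
    pruned and interior queries match classic KNN on the full set."""
    X = rng.normal(scale=0.2, size=(6, 2))
    y = np.array([0, 1, 0, 1, 0, 1])
    m = MutualKNN(k=5).fit(X, y)
    assert len(m.pruned_X_) == 6  # nothing pruned
    c = ClassicKNN(k=5).fit(X, y)
    Q = X.mean(axis=0, keepdims=True) + rng.normal(scale=0.05, size=(10, 2))
    assert np.array_equal(m.predict(Q), c.predict(Q))


def test_mutual_far_query_uses_fallback():
    X = np.array([[0.0], [0.1], [0.2], [0.3]])
    y = np.array(["A", "A", "B", "B"])
    m = MutualKNN(k=1).fit(X, y)
    # far query fails the reciprocal filter for every neighbour
    assert m.predict([[50.0]])[0] in {"A", "B"}


# ---------------------------------------------------------------------------
# ensemble

def test_ensemble_hand_weights():
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0], [13.0], [14.0], [15.0]])
    y = np.array(["B", "A", "A", "B", "B", "B", "B", "B", "B"])
    m = EnsembleKNN().fit(X, y)
    assert m.kmax_ == 3  # round(sqrt(9))
    # sorted neighbour classes at q=0: [B, A, A]
    # B: 1 (k=1) + 1 (k=3 rank 1) = 2; A: 1/log2(3) + 1/log2(4) ~ 1.131
    assert m.predict([[0.0]])[0] == "B"


def test_ensemble_tiny_train_reduces_to_1nn():
    X = np.array([[0.0], [5.0]])
    y = np.array(["A", "B"])
    m = EnsembleKNN().fit(X, y)
    assert m.kmax_ == 1
    assert m.predict([[1.0]])[0] == "A"
    assert m.predict([[4.0]])[0] == "B"


def test_ensemble_kmax_forced_odd():
    ds = generate_synthetic(n=16, d=2, seed=0)  # sqrt -> 4, forced to 3
    m = EnsembleKNN().fit(ds)
    assert m.kmax_ == 3


# ---------------------------------------------------------------------------
# cross-variant properties

def _fit_all(train, seed=0):
    from knnvariants.benchmark import default_variant_configs

    return {
        cfg.variant: make_variant(cfg).fit(train)
        for cfg in default_variant_configs(k=3, seed=seed)
    }


def test_every_variant_deterministic(overlap, rng):
    Q = rng.normal(size=(20, overlap.n_features))
    first = {n: m.predict(Q) for n, m in _fit_all(overlap).items()}
    second = {n: m.predict(Q) for n, m in _fit_all(overlap).items()}
    assert set(first) == ALL_NAMES
    for name in first:
        assert np.array_equal(first[name], second[name]), name


def test_permutation_invariance(rng):
    """With all pairwise distances distinct, training-row order is
    irrelevant for every variant."""
    ds = generate_synthetic(n=40, d=3, class_sep=1.0, seed=77)
    Q = rng.normal(size=(15, 3))
    perm = rng.permutation(ds.n_samples)
    shuffled = ds.take(perm)
    base = {n: m.predict(Q) for n, m in _fit_all(ds).items()}
    moved = {n: m.predict(Q) for n, m in _fit_all(shuffled).items()}
    for name in base:
        assert np.array_equal(base[name], moved[name]), name


def test_multiclass_labels_supported(rng):
    X = rng.normal(size=(60, 3)) + rng.integers(0, 3, size=(60, 1)) * 4.0
    y = np.array(["a", "b", "c"] * 20)
    X[y == "b"] += 8
    X[y == "c"] -= 8
    Q = rng.normal(size=(10, 3))
    for name, model in _fit_all(Dataset(X, y, name="m3")).items():
        pred = model.predict(Q)
        assert set(pred) <= {"a", "b", "c"}, name


def test_variant_config_validation():
    with pytest.raises(ValueError, match="odd"):
        VariantConfig(variant="classic", k=4)
    with pytest.raises(ValueError, match="unknown variant"):
        VariantConfig(variant="knn-magic")
    with pytest.raises(ValueError, match="gmd_exponent"):
        VariantConfig(variant="gmd", gmd_exponent=0.0)
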