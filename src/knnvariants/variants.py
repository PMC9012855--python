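"""The ten k-nearest-neighbour classifier variants.

Every variant follows one contract: construct with its tunables, then
``fit(train)`` and ``predict(queries)``.  ``fit`` accepts either a
:class:`~knnvariants.datasets.Dataset` or an ``(X, y)`` pair; ``predict``
takes a query matrix and returns one class id per row.  All neighbour
searches are brute-force scans — the intended datasets are a few
hundred rows — and all distance ties during neighbour sorting are broken
by training-row index (stable sort), so predictions are deterministic.

Vote ties are resolved in favour of the tied class whose closest member
is nearest the query, then by smallest class id.  The variants accept
any number of classes, although the disease benchmarks they were
compared on are binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distances import pairwise

__all__ = [
    "VariantConfig",
    "VARIANT_NAMES",
    "make_variant",
    "ClassicKNN",
    "AdaptiveKNN",
    "LocallyAdaptiveKNN",
    "FuzzyKNN",
    "KMeansKNN",
    "WeightAdjustedKNN",
    "HassanatKNN",
    "GeneralisedMeanDistanceKNN",
    "MutualKNN",
    "EnsembleKNN",
]

DEFAULT_K_CANDIDATES = (1, 3, 5, 7, 9)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class VariantConfig:
    """Declarative description of one variant and its tunables."""

    variant: str
    k: int = 5
    metric: str = "euclidean"
    fuzzy_m: float = 2.0
    n_clusters: int | None = None
    gmd_exponent: float = 1.0
    kernel: str = "inverse_distance"
    k_candidates: tuple[int, ...] = DEFAULT_K_CANDIDATES
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid names: "
                f"{', '.join(VARIANT_NAMES)}"
            )
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")
        if self.fuzzy_m <= 1:
            raise ValueError("fuzzy_m must exceed 1")
        if self.gmd_exponent == 0:
            raise ValueError("gmd_exponent must be nonzero")
        if self.kernel not in ("inverse_distance", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.k_candidates or any(
            k < 1 or k % 2 == 0 for k in self.k_candidates
        ):
            raise ValueError("k_candidates must be odd integers >= 1")


# ---------------------------------------------------------------------------
# shared machinery

def _as_xy(data, y=None):
    if y is not None:
        return np.asarray(data, dtype=float), np.asarray(y)
    return np.asarray(data.features, dtype=float), np.asarray(data.labels)


class _FittedMixin:
    """Common fitted state: training matrix, labels, class ordering."""

    def _store(self, X, y):
        self.X_ = np.array(X, dtype=float)
        self.y_ = np.array(y)
        self.classes_ = np.unique(self.y_)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain >= 2 classes")
        # class -> position in sorted unique order ("smallest class id" ties)
        self._class_rank = {c: i for i, c in enumerate(self.classes_)}

    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise RuntimeError("call fit() before predict()")

    def _check_k(self, k):
        if k > len(self.X_):
            raise ValueError(
                f"k={k} exceeds the {len(self.X_)} training samples"
            )

    def _neighbour_order(self, dist_row):
        # stable: equal distances resolve by training-row index
        return np.argsort(dist_row, kind="stable")

    def _vote(self, labels, dists):
        """Majority vote; ties go to the class with the nearest member,
        residual ties to the smallest class id."""
        values, counts = np.unique(labels, return_counts=True)
        top = counts.max()
        tied = values[counts == top]
        if len(tied) == 1:
            return tied[0]
        best = None
        key = None
        for c in tied:
            dmin = dists[labels == c].min()
            cand = (dmin, self._class_rank[c])
            if key is None or cand < key:
                key = cand
                best = c
        return best

    def predict(self, Q):
        self._check_fitted()
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        D = pairwise(Q, self.X_, self.metric)
        out = [self._predict_row(Q[i], D[i]) for i in range(len(Q))]
        return np.array(out)


class ClassicKNN(_FittedMixin):
    """Plain majority vote among the k nearest training points."""

    name = "classic"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean"):
        self.k = int(k)
        self.metric = metric

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self._check_k(self.k)
        return self

    def _predict_row(self, q, dist_row):
        order = self._neighbour_order(dist_row)[: self.k]
        return self._vote(self.y_[order], dist_row[order])


class AdaptiveKNN(_FittedMixin):
    """Per-training-point k learned by leave-one-out, inherited by queries.

    During fit, each training point is assigned the smallest candidate k
    whose leave-one-out majority vote classifies it correctly; if none
    does, the largest candidate is stored.  A query inherits the k of
    its nearest training point, then votes classically.
    """

    name = "adaptive"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean", k_candidates=DEFAULT_K_CANDIDATES):
        self.k = int(k)  # unused beyond contract symmetry
        self.metric = metric
        self.k_candidates = tuple(sorted(set(int(k) for k in k_candidates)))

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        n = len(X)
        usable = [k for k in self.k_candidates if k <= n - 1]
        if not usable:
            usable = [1] if n >= 2 else []
        if not usable:
            raise ValueError("need at least 2 training points")
        D = pairwise(X, X, self.metric)
        self.point_k_ = np.empty(n, dtype=int)
        fallback = max(usable)
        for i in range(n):
            row = D[i].copy()
            row[i] = np.inf  # leave self out
            order = self._neighbour_order(row)
            chosen = fallback
            for k in usable:
                nb = order[:k]
                if self._vote(self.y_[nb], row[nb]) == y[i]:
                    chosen = k
                    break
            self.point_k_[i] = chosen
        return self

    def _predict_row(self, q, dist_row):
        nearest = self._neighbour_order(dist_row)[0]
        k = int(self.point_k_[nearest])
        order = self._neighbour_order(dist_row)[:k]
        return self._vote(self.y_[order], dist_row[order])


class LocallyAdaptiveKNN(_FittedMixin):
    """Candidate-k ranking by the majority/second-majority centroid ratio.

    For each candidate k the neighbourhood's majority class C1 and
    second-majority (discrimination) class C2 are found; the score is the
    ratio of the query's distance to the C1 member centroid over its
    distance to the C2 member centroid, with 0 for a single-class
    neighbourhood.  The k with the smallest ratio (most decisively
    separated neighbourhood) wins; ties prefer the smallest k.
    """

    name = "locally_adaptive"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean", k_candidates=DEFAULT_K_CANDIDATES):
        self.k = int(k)
        self.metric = metric
        self.k_candidates = tuple(sorted(set(int(k) for k in k_candidates)))

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self.usable_ = [k for k in self.k_candidates if k <= len(X)]
        if not self.usable_:
            raise ValueError(
                f"no candidate k <= n_train={len(X)} in {self.k_candidates}"
            )
        return self

    def _top_two(self, labels, dists):
        values, counts = np.unique(labels, return_counts=True)
        ranked = sorted(
            zip(values, counts),
            key=lambda vc: (
                -vc[1],
                dists[labels == vc[0]].min(),
                self._class_rank[vc[0]],
            ),
        )
        c1 = ranked[0][0]
        c2 = ranked[1][0] if len(ranked) > 1 else None
        return c1, c2

    def _predict_row(self, q, dist_row):
        order_full = self._neighbour_order(dist_row)
        best = None  # (ratio, k, majority class)
        for k in self.usable_:
            nb = order_full[:k]
            labels = self.y_[nb]
            dists = dist_row[nb]
            c1, c2 = self._top_two(labels, dists)
            if c2 is None:
                ratio = 0.0
            else:
                cent1 = self.X_[nb[labels == c1]].mean(axis=0)
                cent2 = self.X_[nb[labels == c2]].mean(axis=0)
                num = pairwise(q[None, :], cent1[None, :], self.metric)[0, 0]
                den = pairwise(q[None, :], cent2[None, :], self.metric)[0, 0]
                if num == 0.0:
                    ratio = 0.0
                elif den == 0.0:
                    ratio = np.inf
                else:
                    ratio = num / den
            if best is None or ratio < best[0]:
                best = (ratio, k, c1)
        return best[2]


class FuzzyKNN(_FittedMixin):
    """Distance-weighted class memberships over the k nearest neighbours.

    Each neighbour j contributes weight w_j = 1 / d_j^(2/(m-1)) to its
    own class; memberships are the normalised per-class weight sums, so
    they lie in [0, 1] and sum to 1.  A query coinciding with a training
    point receives membership 1 in that point's class.  The fuzzifier m
    (> 1, default 2) controls how sharply closer neighbours dominate.
    """

    name = "fuzzy"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean", fuzzy_m=2.0):
        if fuzzy_m <= 1:
            raise ValueError("fuzzy_m must exceed 1")
        self.k = int(k)
        self.metric = metric
        self.fuzzy_m = float(fuzzy_m)

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self._check_k(self.k)
        return self

    def _memberships_row(self, dist_row):
        order = self._neighbour_order(dist_row)[: self.k]
        labels = self.y_[order]
        dists = dist_row[order]
        mem = np.zeros(len(self.classes_))
        if np.any(dists == 0.0):
            c = labels[np.flatnonzero(dists == 0.0)[0]]
            mem[self._class_rank[c]] = 1.0
            return mem, labels, dists
        w = dists ** (-2.0 / (self.fuzzy_m - 1.0))
        for c, wj in zip(labels, w):
            mem[self._class_rank[c]] += wj
        mem /= mem.sum()
        return mem, labels, dists

    def predict_memberships(self, Q):
        """Per-class membership matrix, columns ordered as ``classes_``."""
        self._check_fitted()
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        D = pairwise(Q, self.X_, self.metric)
        return np.vstack([self._memberships_row(D[i])[0] for i in range(len(Q))])

    def _predict_row(self, q, dist_row):
        mem, labels, dists = self._memberships_row(dist_row)
        top = mem.max()
        tied = self.classes_[mem == top]
        if len(tied) == 1:
            return tied[0]
        in_tied = np.isin(labels, tied)
        return self._vote(labels[in_tied], dists[in_tied])


class KMeansKNN(_FittedMixin):
    """Training set condensed to labelled k-means centroids, then 1-NN.

    Lloyd's algorithm (max 300 iterations, relative shift tolerance
    1e-4) clusters the training features; each surviving centroid takes
    the majority label of its assigned points (ties to the smallest
    class id, empty clusters dropped).  Prediction is the label of the
    nearest centroid.  ``init`` may be ``"spread"`` (deterministic,
    order-independent: evenly spaced rows of the lexicographically
    sorted feature matrix), ``"random"`` (seeded draw of training rows)
    or ``"points"`` (first n_clusters rows verbatim — with
    n_clusters = n_train this is a fixed point of Lloyd's algorithm and
    the classifier reduces to 1-NN).
    """

    name = "kmeans"
    k_dependent = False
    MAX_ITER = 300
    TOL = 1e-4

    def __init__(self, n_clusters=None, metric="euclidean", seed=0, init="spread"):
        self.n_clusters = n_clusters
        self.metric = metric
        self.seed = int(seed)
        if init not in ("spread", "random", "points"):
            raise ValueError(f"unknown init {init!r}")
        self.init = init

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        n = len(X)
        k = self.n_clusters or max(int(round(math.sqrt(n))), 2)
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n_train={n}")
        centroids = self._init_centroids(X, k)
        for _ in range(self.MAX_ITER):
            D = pairwise(X, centroids, "euclidean")
            assign = np.argmin(D, axis=1)
            new = []
            keep = []
            for c in range(len(centroids)):
                members = assign == c
                if members.any():
                    new.append(X[members].mean(axis=0))
                    keep.append(c)
            new = np.vstack(new)
            old = centroids[keep]
            shift = np.linalg.norm(new - old)
            scale = np.linalg.norm(old) or 1.0
            centroids = new
            if shift / scale <= self.TOL:
                break
        D = pairwise(X, centroids, "euclidean")
        assign = np.argmin(D, axis=1)
        cents, labels = [], []
        for c in range(len(centroids)):
            members = assign == c
            if not members.any():
                continue
            values, counts = np.unique(self.y_[members], return_counts=True)
            tied = values[counts == counts.max()]
            labels.append(min(tied, key=lambda v: self._class_rank[v]))
            cents.append(centroids[c])
        self.centroids_ = np.vstack(cents)
        self.centroid_labels_ = np.array(labels)
        return self

    def _init_centroids(self, X, k):
        n = len(X)
        if self.init == "points":
            return X[:k].copy()
        if self.init == "random":
            rng = np.random.default_rng(self.seed)
            return X[rng.choice(n, size=k, replace=False)].copy()
        # spread: evenly spaced rows of the lexicographically sorted matrix,
        # deterministic and invariant to training-row order
        order = np.lexsort(X.T[::-1])
        pos = np.linspace(0, n - 1, k).round().astype(int)
        return X[order[np.unique(pos)]].copy()

    def predict(self, Q):
        self._check_fitted()
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        D = pairwise(Q, self.centroids_, self.metric)
        return self.centroid_labels_[np.argmin(D, axis=1)]


class WeightAdjustedKNN(_FittedMixin):
    """Kernel-weighted voting: nearer neighbours count for more.

    ``inverse_distance`` weights by 1/(d + 1e-9); ``gaussian`` by
    exp(-d^2 / (2 sigma^2)) with sigma the mean neighbour distance of
    the query.  The class with the largest weight sum wins.
    """

    name = "weight_adjusted"
    k_dependent = True
    EPS = 1e-9

    def __init__(self, k=5, metric="euclidean", kernel="inverse_distance"):
        if kernel not in ("inverse_distance", "gaussian"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.k = int(k)
        self.metric = metric
        self.kernel = kernel

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self._check_k(self.k)
        return self

    def _predict_row(self, q, dist_row):
        order = self._neighbour_order(dist_row)[: self.k]
        labels = self.y_[order]
        dists = dist_row[order]
        if self.kernel == "inverse_distance":
            w = 1.0 / (dists + self.EPS)
        else:
            sigma = dists.mean()
            w = (
                np.exp(-(dists**2) / (2.0 * sigma**2))
                if sigma > 0
                else np.ones_like(dists)
            )
        totals = np.zeros(len(self.classes_))
        for c, wj in zip(labels, w):
            totals[self._class_rank[c]] += wj
        top = totals.max()
        tied = self.classes_[totals == top]
        if len(tied) == 1:
            return tied[0]
        in_tied = np.isin(labels, tied)
        return self._vote(labels[in_tied], dists[in_tied])


class HassanatKNN(ClassicKNN):
    """Classic majority voting under the Hassanat distance metric."""

    name = "hassanat"

    def __init__(self, k=5, metric="hassanat"):
        super().__init__(k=k, metric="hassanat")


class GeneralisedMeanDistanceKNN(_FittedMixin):
    """Per-class nested local-mean distances pooled by a generalised mean.

    For each class the k nearest members are sorted by distance; the
    nested local mean vectors m_j average the first j of them
    (j = 1..k).  The class score is the generalised mean with exponent p
    of the distances from the query to each m_j (p = 1, the arithmetic
    mean, by default; p = 0 is the geometric mean).  The class with the
    smallest score is predicted.  With k = 1 this is exactly 1-NN for
    any exponent.
    """

    name = "gmd"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean", gmd_exponent=1.0):
        self.k = int(k)
        self.metric = metric
        self.gmd_exponent = float(gmd_exponent)

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self.class_members_ = {
            c: np.flatnonzero(self.y_ == c) for c in self.classes_
        }
        for c, idx in self.class_members_.items():
            if len(idx) == 0:
                raise ValueError(f"class {c!r} has no training members")
        return self

    def _gen_mean(self, d):
        p = self.gmd_exponent
        d = np.asarray(d, dtype=float)
        if p == 0.0:
            if np.any(d == 0.0):
                return 0.0
            return float(np.exp(np.mean(np.log(d))))
        if p < 0 and np.any(d == 0.0):
            return 0.0  # limit of the generalised mean
        return float(np.mean(d**p) ** (1.0 / p))

    def _predict_row(self, q, dist_row):
        best = None
        for c in self.classes_:
            idx = self.class_members_[c]
            sub = dist_row[idx]
            order = np.argsort(sub, kind="stable")
            kc = min(self.k, len(idx))
            members = self.X_[idx[order[:kc]]]
            cum = np.cumsum(members, axis=0) / np.arange(1, kc + 1)[:, None]
            dj = pairwise(q[None, :], cum, self.metric)[0]
            score = self._gen_mean(dj)
            key = (score, self._class_rank[c])
            if best is None or key < best[0]:
                best = (key, c)
        return best[1]


class MutualKNN(_FittedMixin):
    """Training set pruned to mutual k-nearest-neighbour points.

    Two training points are mutual neighbours when each appears in the
    other's k-NN list; points with no mutual partner are discarded as
    noise at fit time.  At prediction the k nearest surviving points are
    filtered to those that would reciprocally count the query among
    their own k neighbours; the vote runs over the filtered set, falling
    back to a classic vote over the k surviving neighbours when the
    filter removes everyone.
    """

    name = "mutual"
    k_dependent = True

    def __init__(self, k=5, metric="euclidean"):
        self.k = int(k)
        self.metric = metric

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        self._check_k(self.k)
        n = len(X)
        D = pairwise(X, X, self.metric)
        np.fill_diagonal(D, np.inf)
        k = min(self.k, n - 1)
        lists = [set(self._neighbour_order(D[i])[:k].tolist()) for i in range(n)]
        keep = np.array(
            [any(i in lists[j] for j in lists[i]) for i in range(n)]
        )
        if not keep.any():
            raise ValueError(
                "mutual-neighbour pruning removed every training point; "
                f"k={self.k} is too small for this data"
            )
        self.pruned_X_ = self.X_[keep]
        self.pruned_y_ = self.y_[keep]
        m = len(self.pruned_X_)
        Dp = pairwise(self.pruned_X_, self.pruned_X_, self.metric)
        np.fill_diagonal(Dp, np.inf)
        kk = min(self.k, m - 1) if m > 1 else 1
        self.radius_ = np.array(
            [np.sort(Dp[i])[kk - 1] if m > 1 else np.inf for i in range(m)]
        )
        return self

    def predict(self, Q):
        self._check_fitted()
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        D = pairwise(Q, self.pruned_X_, self.metric)
        out = []
        k = min(self.k, len(self.pruned_X_))
        for i in range(len(Q)):
            order = self._neighbour_order(D[i])[:k]
            dists = D[i][order]
            kept = dists <= self.radius_[order]
            if kept.any():
                out.append(self._vote(self.pruned_y_[order[kept]], dists[kept]))
            else:
                out.append(self._vote(self.pruned_y_[order], dists))
        return np.array(out)


class EnsembleKNN(_FittedMixin):
    """Rank-weighted voting pooled over k = 1, 3, ..., Kmax.

    Kmax is round(sqrt(n_train)) forced odd (minimum 1), so no k needs
    choosing.  For each odd k up to Kmax the r-th nearest neighbour adds
    1/log2(r + 1) to its class; the class with the largest cumulative
    weight over all the k-rounds wins.
    """

    name = "ensemble"
    k_dependent = False

    def __init__(self, metric="euclidean", k=None):
        self.metric = metric
        self.k = k  # accepted for contract symmetry; ignored

    def fit(self, data, y=None):
        X, y = _as_xy(data, y)
        self._store(X, y)
        kmax = int(round(math.sqrt(len(X))))
        if kmax % 2 == 0:
            kmax -= 1
        self.kmax_ = max(kmax, 1)
        # aggregate the per-round rank weights once; rank r appears in
        # every round whose k reaches it
        weights = np.zeros(self.kmax_)
        for k in range(1, self.kmax_ + 1, 2):
            for r in range(1, k + 1):
                weights[r - 1] += 1.0 / math.log2(r + 1)
        self._rank_weights = weights
        return self

    def _predict_row(self, q, dist_row):
        order = self._neighbour_order(dist_row)[: self.kmax_]
        labels = self.y_[order]
        totals = np.zeros(len(self.classes_))
        for lbl, w in zip(labels, self._rank_weights):
            totals[self._class_rank[lbl]] += w
        top = totals.max()
        tied = self.classes_[totals == top]
        if len(tied) == 1:
            return tied[0]
        in_tied = np.isin(labels, tied)
        return self._vote(labels[in_tied], dist_row[order][in_tied])


_REGISTRY = {
    cls.name: cls
    for cls in (
        ClassicKNN,
        AdaptiveKNN,
        LocallyAdaptiveKNN,
        FuzzyKNN,
        KMeansKNN,
        WeightAdjustedKNN,
        HassanatKNN,
        GeneralisedMeanDistanceKNN,
        MutualKNN,
        EnsembleKNN,
    )
}

VARIANT_NAMES = tuple(_REGISTRY)


def make_variant(config: VariantConfig):
    """Instantiate the classifier a :class:`VariantConfig` describes."""
    v = config.variant
    if v == "classic":
        return ClassicKNN(k=config.k, metric=config.metric)
    if v == "adaptive":
        return AdaptiveKNN(
            k=config.k, metric=config.metric, k_candidates=config.k_candidates
        )
    if v == "locally_adaptive":
        return LocallyAdaptiveKNN(
            k=config.k, metric=config.metric, k_candidates=config.k_candidates
        )
    if v == "fuzzy":
        return FuzzyKNN(k=config.k, metric=config.metric, fuzzy_m=config.fuzzy_m)
    if v == "kmeans":
        return KMeansKNN(
            n_clusters=config.n_clusters, metric=config.metric, seed=config.seed
        )
    if v == "weight_adjusted":
        return WeightAdjustedKNN(
            k=config.k, metric=config.metric, kernel=config.kernel
        )
    if v == "hassanat":
        return HassanatKNN(k=config.k)
    if v == "gmd":
        return GeneralisedMeanDistanceKNN(
            k=config.k, metric=config.metric, gmd_exponent=config.gmd_exponent
        )
    if v == "mutual":
        return MutualKNN(k=config.k, metric=config.metric)
    if v == "ensemble":
        return EnsembleKNN(metric=config.metric)
    raise ValueError(f"unknown variant {v!r}")  # unreachable
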