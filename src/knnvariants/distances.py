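"""Distance functions shared by every classifier variant.

Three metrics are provided: Euclidean, Manhattan (city-block) and the
Hassanat metric.  The Hassanat metric is bounded per dimension: each
coordinate contributes

    1 - (1 + min(x_i, y_i)) / (1 + max(x_i, y_i))            if min >= 0
    1 - (1 + min + |min|) / (1 + max + |min|)                otherwise

so every term lies in [0, 1) and the total is strictly below the number
of dimensions.  This makes the metric insensitive to the absolute scale
of individual features, which is why it copes well with unscaled mixed
tabular data.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "euclidean",
    "manhattan",
    "hassanat",
    "get_metric",
    "pairwise",
    "METRICS",
]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return x, y


def euclidean(x, y) -> float:
    """Square root of the summed squared coordinate differences."""
    x, y = _check_pair(x, y)
    return float(np.sqrt(np.sum((x - y) ** 2)))


def manhattan(x, y) -> float:
    """Summed absolute coordinate differences."""
    x, y = _check_pair(x, y)
    return float(np.sum(np.abs(x - y)))


def hassanat(x, y) -> float:
    """Hassanat distance: sum of bounded per-dimension terms."""
    x, y = _check_pair(x, y)
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    shift = np.where(lo < 0, -lo, 0.0)
    return float(np.sum(1.0 - (1.0 + lo + shift) / (1.0 + hi + shift)))


def _pairwise_euclidean(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(Q**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * Q @ X.T
    )
    return np.sqrt(np.maximum(d2, 0.0))


def _pairwise_manhattan(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.sum(np.abs(Q[:, None, :] - X[None, :, :]), axis=2)


def _pairwise_hassanat(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    a = Q[:, None, :]
    b = X[None, :, :]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    shift = np.where(lo < 0, -lo, 0.0)
    return np.sum(1.0 - (1.0 + lo + shift) / (1.0 + hi + shift), axis=2)


METRICS: dict[str, Callable] = {
    "euclidean": euclidean,
    "manhattan": manhattan,
    "hassanat": hassanat,
}

_PAIRWISE = {
    "euclidean": _pairwise_euclidean,
    "manhattan": _pairwise_manhattan,
    "hassanat": _pairwise_hassanat,
}


def get_metric(name: str) -> Callable:
    """Look up a metric by name; raises ``ValueError`` for unknown names."""
    try:
        return METRICS[name]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; choose from {sorted(METRICS)}"
        ) from None


def pairwise(Q, X, metric: str = "euclidean") -> np.ndarray:
    """Distance matrix between query rows ``Q`` and training rows ``X``.

    Returns an ``(n_queries, n_train)`` array.  Brute force by design: the
    datasets this package targets are a few hundred rows.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Q.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: queries have {Q.shape[1]} features, "
            f"training set has {X.shape[1]}"
        )
    try:
        fn = _PAIRWISE[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_PAIRWISE)}"
        ) from None
    return fn(Q, X)
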