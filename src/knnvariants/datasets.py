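"""Tabular dataset handling: loading, preprocessing, splitting, synthesis.

A :class:`Dataset` is the universal input of the package: a numeric
feature matrix plus a class-label vector.  Real data enters through
:func:`read_csv_dataset`; controlled two-class Gaussian mixtures for
testing and demonstration come from :func:`generate_synthetic`; the
published benchmark result tables are exposed through
:func:`load_paper_tables`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _paper_tables
from .metrics import MeasureTable

__all__ = [
    "Dataset",
    "SplitSpec",
    "PaperTables",
    "read_csv_dataset",
    "preprocess",
    "split",
    "generate_synthetic",
    "load_paper_tables",
]


@dataclass(frozen=True)
class Dataset:
    """A tabular classification dataset.

    Parameters
    ----------
    features : ndarray, shape (n_samples, n_features)
        Numeric feature matrix (unitless after scaling).
    labels : ndarray, shape (n_samples,)
        Class identifier per row; at least two distinct values.
    feature_names : tuple of str
        One name per feature column.
    name : str
        Identifier used in reports.
    positive_label : optional
        The class treated as "positive" by precision/recall; defaults to
        the label value 1 when present, else the largest class id.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()
    name: str = "dataset"
    positive_label: object = None

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if y.shape != (n,):
            raise ValueError(
                f"labels length {y.shape} does not match n_samples {n}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 distinct label values")
        names = tuple(self.feature_names) or tuple(
            f"f{i}" for i in range(d)
        )
        if len(names) != d:
            raise ValueError("feature_names length must match n_features")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "feature_names", names)
        if self.positive_label is None:
            classes = np.unique(y)
            pos = 1 if 1 in classes else classes[-1]
            object.__setattr__(self, "positive_label", pos)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def take(self, idx, suffix: str = "") -> "Dataset":
        """Row subset as a new Dataset (order of ``idx`` preserved)."""
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            name=self.name + suffix,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Holdout split configuration.

    The default — stratified 70/30 holdout with seed 42 — is this
    package's own reproducible convention, configurable throughout.
    """

    test_fraction: float = 0.3
    seed: int = 42
    stratified: bool = True

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PaperTables:
    """The published 10-variant x 8-dataset result tables plus ANOVA rows."""

    accuracy_table: MeasureTable
    precision_table: MeasureTable
    recall_table: MeasureTable
    anova_reference: dict = field(repr=False, default_factory=dict)

    def table(self, measure: str) -> MeasureTable:
        return {
            "accuracy": self.accuracy_table,
            "precision": self.precision_table,
            "recall": self.recall_table,
        }[measure]


def read_csv_dataset(
    path,
    label_column: str,
    positive_label=None,
    name: str | None = None,
    allow_missing: bool = False,
    encode_categorical: bool = False,
) -> Dataset:
    """Read a headered CSV into a Dataset.

    All non-label columns become features, coerced to numbers.  A cell
    that cannot be coerced raises a parse error naming its row and
    column, unless ``encode_categorical`` is set, in which case the
    whole column is integer-encoded (mode imputation of its gaps is
    left to :func:`preprocess`).  Empty cells raise unless
    ``allow_missing``; then they survive as NaN for ``preprocess`` to
    fill.  Rows keep file order; labels are taken verbatim.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise KeyError(
            f"label column {label_column!r} not found in header "
            f"{list(df.columns)}"
        )
    y = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    if feats.shape[1] == 0:
        raise ValueError("no feature columns besides the label")
    X = np.empty(feats.shape, dtype=float)
    for j, col in enumerate(feats.columns):
        series = feats[col]
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna() & series.notna()
        if bad.any():
            if encode_categorical:
                codes, _ = pd.factorize(series)
                coerced = pd.Series(codes, dtype=float)
                coerced[series.isna().to_numpy()] = np.nan
            else:
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value {series.iloc[row]!r} in feature "
                    f"column {col!r}, row {row}"
                )
        X[:, j] = coerced.to_numpy(dtype=float)
    if np.isnan(X).any() and not allow_missing:
        row, j = (int(v) for v in np.argwhere(np.isnan(X))[0])
        raise ValueError(
            f"missing value in feature column {feats.columns[j]!r}, row "
            f"{row}; pass allow_missing=True and impute via preprocess()"
        )
    return Dataset(
        features=X,
        labels=y,
        feature_names=tuple(feats.columns),
        name=name or str(path),
        positive_label=positive_label,
    )


def preprocess(
    ds: Dataset,
    impute: str = "median_mode",
    scale: str = "minmax",
) -> Dataset:
    """Impute missing cells and rescale features.

    ``impute='median_mode'`` fills numeric gaps with the column median
    (the mode path applies to categorical columns before encoding, which
    :func:`read_csv_dataset` already integer-encodes); ``scale='minmax'``
    maps each feature to [0, 1], constant columns to 0; ``'zscore'``
    standardises to zero mean, unit variance (constant columns to 0).
    Labels are untouched.  Idempotent for minmax on already-scaled data.
    """
    if impute not in ("none", "median_mode"):
        raise ValueError(f"unknown impute mode {impute!r}")
    if scale not in ("none", "minmax", "zscore"):
        raise ValueError(f"unknown scale mode {scale!r}")
    X = np.array(ds.features, dtype=float, copy=True)
    if impute == "median_mode":
        for j in range(X.shape[1]):
            col = X[:, j]
            gaps = np.isnan(col)
            if gaps.any():
                filled = np.nanmedian(col) if not gaps.all() else 0.0
                col[gaps] = filled
    elif np.isnan(X).any():
        raise ValueError("missing values present and imputation disabled")
    if scale == "minmax":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        safe = np.where(rng == 0, 1.0, rng)
        X = np.where(rng == 0, 0.0, (X - lo) / safe)
    elif scale == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        safe = np.where(sd == 0, 1.0, sd)
        X = np.where(sd == 0, 0.0, (X - mu) / safe)
    return replace(ds, features=X)


def split(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Seeded (optionally stratified) holdout split.

    The two partitions are disjoint and exhaustive; with stratification
    each class contributes its proportional share to the test set,
    rounded to within one sample per class.
    """
    n = ds.n_samples
    n_test = int(round(n * spec.test_fraction))
    if n_test < 1 or n_test >= n:
        raise ValueError(
            f"test_fraction {spec.test_fraction} leaves an empty partition "
            f"for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        test_idx: list[int] = []
        classes = ds.classes
        # per-class proportional allocation, largest remainder for the rest
        wanted = {}
        for c in classes:
            members = np.flatnonzero(ds.labels == c)
            wanted[c] = spec.test_fraction * len(members)
        base = {c: int(np.floor(w)) for c, w in wanted.items()}
        short = n_test - sum(base.values())
        order = sorted(
            classes, key=lambda c: -(wanted[c] - base[c])
        )
        for c in order[: max(short, 0)]:
            base[c] += 1
        for c in classes:
            members = np.flatnonzero(ds.labels == c)
            if len(members) >= 2:
                # every class with >= 2 members lands in both partitions
                k = min(max(base[c], 1), len(members) - 1)
            else:
                k = 0
            if k > 0:
                picked = rng.choice(members, size=k, replace=False)
                test_idx.extend(picked.tolist())
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
    else:
        perm = rng.permutation(n)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[perm[:n_test]] = True
    if test_mask.all() or not test_mask.any():
        raise ValueError("split produced an empty partition")
    train = ds.take(np.flatnonzero(~test_mask), suffix=":train")
    test = ds.take(np.flatnonzero(test_mask), suffix=":test")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training partition lost all but one class")
    return train, test


def generate_synthetic(
    n: int = 400,
    d: int = 8,
    class_sep: float = 2.0,
    class_balance: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    name: str | None = None,
) -> Dataset:
    """Two-class Gaussian mixture emulating a binary disease dataset.

    Class 0 is centred at the origin, class 1 at ``class_sep * noise_sd``
    in every dimension; both classes share isotropic spread ``noise_sd``.
    ``class_balance`` is the expected fraction of class-1 rows (the count
    is fixed at ``round(n * class_balance)`` for determinism).  The
    defaults — n=400, d=8, unit noise — mirror the size and width of the
    mid-sized disease tables the benchmark targets, with ``class_sep=2``
    giving realistically overlapping classes.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if d < 1:
        raise ValueError("need d >= 1")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie in (0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if class_sep < 0:
        raise ValueError("class_sep must be non-negative")
    rng = np.random.default_rng(seed)
    n1 = min(max(int(round(n * class_balance)), 1), n - 1)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n1, replace=False)] = 1
    X = rng.normal(scale=noise_sd, size=(n, d))
    X[y == 1] += class_sep * noise_sd
    return Dataset(
        features=X,
        labels=y,
        name=name or f"synthetic(n={n},d={d},sep={class_sep},seed={seed})",
        positive_label=1,
    )


def load_paper_tables() -> PaperTables:
    """The published accuracy/precision/recall tables and ANOVA reference.

    Values are exactly as printed (percent, two decimals); the known
    internal inconsistencies of the published tables are preserved.
    Pure: no I/O beyond the embedded module.
    """
    def mk(values, measure):
        df = pd.DataFrame(
            np.asarray(values, dtype=float).T,
            index=list(_paper_tables.VARIANTS),
            columns=list(_paper_tables.DATASETS),
        )
        return MeasureTable(values=df, measure=measure)

    return PaperTables(
        accuracy_table=mk(_paper_tables.ACCURACY, "accuracy"),
        precision_table=mk(_paper_tables.PRECISION, "precision"),
        recall_table=mk(_paper_tables.RECALL, "recall"),
        anova_reference={
            k: dict(v) for k, v in _paper_tables.ANOVA_REFERENCE.items()
        },
    )
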