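"""Evaluation measures: confusion counts, accuracy/precision/recall,
the Relative Performance Index (RPI), table summaries, and one-way ANOVA.

The RPI compares classifier variants across a collection of datasets on
one measure.  For variant v with value a_i on dataset i, and a_i* the
minimum value any variant attains on dataset i,

    RPI(v) = sum_i (a_i - a_i*) / d

over the d datasets: the mean excess over the per-dataset worst
performer, in the measure's own units (percentage points here).  It is
zero exactly for a variant that is worst everywhere, translation
invariant per dataset column, and higher is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MeasureTable",
    "RPIResult",
    "AnovaRow",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "evaluate",
    "rpi",
    "row_average",
    "win_counts",
    "one_way_anova",
]

MEASURES = ("accuracy", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MeasureTable:
    """Variants x datasets matrix of one measure, in percent.

    Wraps a DataFrame whose rows are variant names and columns dataset
    names.  All summary operations (averages, win counts, RPI, ANOVA)
    consume this shape.
    """

    values: pd.DataFrame
    measure: str = "accuracy"

    def __post_init__(self):
        df = self.values
        if df.isna().any().any():
            raise ValueError("MeasureTable must have no missing cells")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("row/column names must be unique")
        object.__setattr__(self, "values", df.astype(float))

    @property
    def variants(self) -> list[str]:
        return list(self.values.index)

    @property
    def dataset_names(self) -> list[str]:
        return list(self.values.columns)

    def cell(self, variant: str, dataset: str) -> float:
        return float(self.values.loc[variant, dataset])


@dataclass(frozen=True)
class RPIResult:
    """Per-variant RPI scores (percentage points, >= 0)."""

    scores: pd.Series
    measure: str = "accuracy"

    def __getitem__(self, variant: str) -> float:
        return float(self.scores[variant])


@dataclass(frozen=True)
class AnovaRow:
    between_SS: float
    within_SS: float
    total_SS: float
    df_between: int
    df_within: int
    F: float
    p: float
    measure: str = ""


def confusion(y_true, y_pred, positive) -> ConfusionCounts:
    """Tally TP/TN/FP/FN against the named positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"shape mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise ValueError("accuracy undefined on zero samples")
    return (c.TP + c.TN) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN (with a warning) when nothing was predicted
    positive — never silently 0 or 1."""
    if c.TP + c.FP == 0:
        warnings.warn(
            "precision undefined (no positive predictions); reporting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN (with a warning) when the positive class is
    absent from the truth."""
    if c.TP + c.FN == 0:
        warnings.warn(
            "recall undefined (positive class absent); reporting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return c.TP / (c.TP + c.FN)


def evaluate(y_true, y_pred, positive=None) -> dict[str, float]:
    """All three measures at once, on the [0, 1] scale.

    Binary convention: measures are computed on the positive class.  For
    more than two classes a one-vs-rest macro average is used — an
    extension beyond the binary benchmark this package reproduces.
    """
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if positive is not None or len(classes) <= 2:
        if positive is None:
            positive = 1 if 1 in classes else classes[-1]
        c = confusion(y_true, y_pred, positive)
        return {
            "accuracy": accuracy(c),
            "precision": precision(c),
            "recall": recall(c),
        }
    per_class = [evaluate(y_true, y_pred, positive=c) for c in classes]
    out = {"accuracy": float(np.mean(np.asarray(y_pred) == y_true))}
    for m in ("precision", "recall"):
        vals = np.array([pc[m] for pc in per_class])
        out[m] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
    return out


def rpi(table: MeasureTable) -> RPIResult:
    """Relative Performance Index per variant (see module docstring)."""
    df = table.values
    col_min = df.min(axis=0)
    scores = (df - col_min).sum(axis=1) / df.shape[1]
    return RPIResult(scores=scores, measure=table.measure)


def row_average(table: MeasureTable) -> pd.Series:
    """Arithmetic mean across datasets, per variant."""
    return table.values.mean(axis=1)


def win_counts(table: MeasureTable) -> pd.Series:
    """Datasets on which each variant attains the column maximum.

    Ties count for every variant holding the maximum, so the counts can
    sum to more than the number of datasets.
    """
    df = table.values
    wins = (df == df.max(axis=0)).sum(axis=1)
    return wins.astype(int)


def one_way_anova(table: MeasureTable) -> AnovaRow:
    """One-way ANOVA with variants as groups, per-dataset values as
    observations.

    F = MS_between / MS_within with (groups-1, N-groups) degrees of
    freedom; p from the F distribution.  Zero within-group variance with
    non-zero between-group variance yields F = inf, p = 0.
    """
    df = table.values
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 variants and 2 datasets")
    groups = df.to_numpy()
    grand = groups.mean()
    n_per = groups.shape[1]
    between = n_per * np.sum((groups.mean(axis=1) - grand) ** 2)
    within = np.sum((groups - groups.mean(axis=1, keepdims=True)) ** 2)
    df_b = groups.shape[0] - 1
    df_w = groups.size - groups.shape[0]
    if within == 0.0:
        F = 0.0 if between == 0.0 else float("inf")
        p = 1.0 if between == 0.0 else 0.0
    else:
        F = (between / df_b) / (within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaRow(
        between_SS=float(between),
        within_SS=float(within),
        total_SS=float(between + within),
        df_between=df_b,
        df_within=df_w,
        F=float(F),
        p=p,
        measure=table.measure,
    )
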