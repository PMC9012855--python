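"""Benchmark harness: every variant on every dataset over a k grid.

The protocol mirrors the published comparison: each k-dependent variant
is evaluated at k in {1, 3, 5, 7, 9}, the best value per measure is
kept (``per-measure`` selection; ``per-accuracy`` selection — evaluating
precision and recall at the accuracy-optimal k — is available as a
flag), and the resulting variants x datasets tables feed the summary
statistics: row averages, win counts, RPI and one-way ANOVA.

The summary pipeline also accepts externally supplied measure tables
(see :func:`summarize_tables`), which is how the published tables are
pushed through the same statistics without access to the original
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .datasets import Dataset, SplitSpec, split
from .metrics import MeasureTable, evaluate
from .variants import VariantConfig, make_variant

__all__ = [
    "GridSpec",
    "BenchmarkResult",
    "run_grid",
    "select_best",
    "run_benchmark",
    "summarize_tables",
    "write_report",
    "default_variant_configs",
]

log = logging.getLogger(__name__)

K_GRID_DEFAULT = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class GridSpec:
    """k grid, measures and split protocol for one benchmark run."""

    k_grid: tuple[int, ...] = K_GRID_DEFAULT
    measures: tuple[str, ...] = ("accuracy", "precision", "recall")
    split: SplitSpec = field(default_factory=SplitSpec)
    best_k_by: str = "per_measure"  # or "accuracy"

    def __post_init__(self):
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise ValueError("k_grid must be non-empty with k >= 1")
        bad = set(self.measures) - set(metrics.MEASURES)
        if bad:
            raise ValueError(f"unknown measures {sorted(bad)}")
        if self.best_k_by not in ("per_measure", "accuracy"):
            raise ValueError("best_k_by must be 'per_measure' or 'accuracy'")


@dataclass(frozen=True)
class SummaryStats:
    """Averages, win counts, RPI and ANOVA for one set of measure tables."""

    tables: dict[str, MeasureTable]
    averages: dict[str, pd.Series]
    wins: dict[str, pd.Series]
    rpi: dict[str, metrics.RPIResult]
    anova: dict[str, metrics.AnovaRow]


@dataclass(frozen=True)
class BenchmarkResult:
    """Full benchmark output: best-k tables plus their summaries."""

    tables: dict[str, MeasureTable]
    best_k: pd.DataFrame  # columns: variant, dataset, measure, k, value
    summary: SummaryStats
    run_log: pd.DataFrame  # one row per variant x dataset x k x measure


def default_variant_configs(k: int = 5, seed: int = 0) -> list[VariantConfig]:
    """One config per variant, in the canonical comparison order."""
    return [
        VariantConfig(variant="classic", k=k),
        VariantConfig(variant="adaptive", k=k),
        VariantConfig(variant="locally_adaptive", k=k),
        VariantConfig(variant="fuzzy", k=k),
        VariantConfig(variant="kmeans", seed=seed),
        VariantConfig(variant="weight_adjusted", k=k),
        VariantConfig(variant="hassanat", k=k, metric="hassanat"),
        VariantConfig(variant="gmd", k=k),
        VariantConfig(variant="mutual", k=k),
        VariantConfig(variant="ensemble"),
    ]


def _variant_is_k_dependent(config: VariantConfig) -> bool:
    return config.variant not in ("kmeans", "ensemble")


def run_grid(
    train: Dataset,
    test: Dataset,
    config: VariantConfig,
    grid: GridSpec,
) -> pd.DataFrame:
    """Evaluate one variant over the grid.

    Returns a tidy frame with columns (k, measure, value); k-independent
    variants (kmeans, ensemble) get a single row set with k = -1
    (recorded as not applicable downstream).
    """
    ks: list[int]
    if _variant_is_k_dependent(config):
        ks = [k for k in grid.k_grid if k <= train.n_samples]
        if not ks:
            raise ValueError(
                f"no grid k fits n_train={train.n_samples} "
                f"(variant={config.variant})"
            )
    else:
        ks = [-1]
    rows = []
    for k in ks:
        cfg = config if k == -1 else VariantConfig(
            **{**config.__dict__, "k": k}
        )
        try:
            model = make_variant(cfg).fit(train)
            y_pred = model.predict(test.features)
        except Exception as exc:
            raise RuntimeError(
                f"variant={config.variant} dataset={train.name} k={k}: {exc}"
            ) from exc
        scores = evaluate(test.labels, y_pred, positive=test.positive_label)
        for m in grid.measures:
            rows.append({"k": k, "measure": m, "value": scores[m]})
    return pd.DataFrame(rows)


def select_best(per_k: pd.DataFrame, measure: str) -> tuple[float, int]:
    """Best value over the grid for one measure; ties prefer smallest k."""
    sub = per_k[per_k["measure"] == measure]
    if sub.empty:
        raise ValueError(f"measure {measure!r} absent from grid results")
    sub = sub.sort_values("k", kind="stable")
    vals = sub["value"].to_numpy()
    if np.all(np.isnan(vals)):
        return float("nan"), int(sub["k"].iloc[0])
    best_i = int(np.nanargmax(vals))
    return float(vals[best_i]), int(sub["k"].iloc[best_i])


def run_benchmark(
    datasets: list[Dataset],
    variants: list[VariantConfig] | None = None,
    grid: GridSpec | None = None,
) -> BenchmarkResult:
    """Run every variant on every dataset and assemble the full report.

    Datasets that fail to split are skipped with a warning and excluded
    from all tables.  Fully deterministic given the seeds in the grid's
    split spec and the variant configs.
    """
    grid = grid or GridSpec()
    variants = variants if variants is not None else default_variant_configs()
    if not datasets or not variants:
        raise ValueError("need at least one dataset and one variant")

    usable: list[tuple[Dataset, Dataset, Dataset]] = []
    for ds in datasets:
        try:
            tr, te = split(ds, grid.split)
        except ValueError as exc:
            log.warning("skipping dataset %s: %s", ds.name, exc)
            continue
        usable.append((ds, tr, te))
    if not usable:
        raise ValueError("every dataset failed preprocessing/splitting")

    cells: dict[str, dict[str, dict[str, float]]] = {
        m: {} for m in grid.measures
    }
    best_rows = []
    log_rows = []
    for config in variants:
        vname = config.variant
        for ds, tr, te in usable:
            per_k = run_grid(tr, te, config, grid)
            for _, row in per_k.iterrows():
                log_rows.append(
                    {
                        "variant": vname,
                        "dataset": ds.name,
                        "k": int(row["k"]),
                        "measure": row["measure"],
                        "value": row["value"],
                    }
                )
            if grid.best_k_by == "accuracy" and "accuracy" in grid.measures:
                _, k_acc = select_best(per_k, "accuracy")
                for m in grid.measures:
                    sub = per_k[
                        (per_k["measure"] == m) & (per_k["k"] == k_acc)
                    ]
                    value = float(sub["value"].iloc[0])
                    cells[m].setdefault(vname, {})[ds.name] = value * 100.0
                    best_rows.append(
                        {
                            "variant": vname,
                            "dataset": ds.name,
                            "measure": m,
                            "k": k_acc,
                            "value": value * 100.0,
                        }
                    )
            else:
                for m in grid.measures:
                    value, k_best = select_best(per_k, m)
                    cells[m].setdefault(vname, {})[ds.name] = value * 100.0
                    best_rows.append(
                        {
                            "variant": vname,
                            "dataset": ds.name,
                            "measure": m,
                            "k": k_best,
                            "value": value * 100.0,
                        }
                    )

    tables = {}
    for m in grid.measures:
        df = pd.DataFrame(cells[m]).T  # variants x datasets
        df = df.loc[[c.variant for c in variants], [d.name for d, _, _ in usable]]
        tables[m] = MeasureTable(values=df, measure=m)
    summary = summarize_tables(tables)
    return BenchmarkResult(
        tables=tables,
        best_k=pd.DataFrame(best_rows),
        summary=summary,
        run_log=pd.DataFrame(log_rows),
    )


def summarize_tables(tables: dict[str, MeasureTable]) -> SummaryStats:
    """Averages, win counts, RPI and ANOVA from measure tables.

    This is the fixture path: feed it externally supplied tables (for
    instance the published ones) and it produces the same summary
    statistics as a full benchmark run.
    """
    averages = {m: metrics.row_average(t) for m, t in tables.items()}
    wins = {m: metrics.win_counts(t) for m, t in tables.items()}
    rpis = {m: metrics.rpi(t) for m, t in tables.items()}
    anova = {
        m: metrics.one_way_anova(t)
        for m, t in tables.items()
        if t.values.shape[0] >= 2 and t.values.shape[1] >= 2
    }
    return SummaryStats(
        tables=tables, averages=averages, wins=wins, rpi=rpis, anova=anova
    )


def write_report(result: BenchmarkResult, outdir) -> list[str]:
    """Write the seven report CSVs; returns the file names written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []

    def emit(name, df):
        path = os.path.join(outdir, name)
        df.to_csv(path, float_format="%.6f")
        written.append(name)

    for m, t in result.tables.items():
        emit(f"{m}.csv", t.values)
    emit("best_k.csv", result.best_k.set_index(["variant", "dataset", "measure"]))
    emit(
        "rpi.csv",
        pd.DataFrame({m: r.scores for m, r in result.summary.rpi.items()}),
    )
    emit(
        "win_counts.csv",
        pd.DataFrame(result.summary.wins),
    )
    anova_df = pd.DataFrame(
        {
            m: {
                "between_SS": a.between_SS,
                "within_SS": a.within_SS,
                "total_SS": a.total_SS,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "F": a.F,
                "p": a.p,
            }
            for m, a in result.summary.anova.items()
        }
    ).T
    emit("anova.csv", anova_df)
    return written
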