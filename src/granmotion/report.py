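"""Condition-level summaries and statistical comparisons.

Mirrors the reporting conventions of the analysis: histograms plus
empirical cumulative probability curves per metric, mean +/- SEM for
normal-looking data, median (with SEM and a bootstrap SE of the median)
for exponential-like data, class-fraction bars with n, and two-sample
t / Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted sample values and P(X <= x) at each.

    Right-continuous and nondecreasing; evaluates to 1 at the sample max.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("empty sample")
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def ecdf_eval(values: Sequence[float], at: Sequence[float]) -> np.ndarray:
    """Evaluate the ECDF of ``values`` at the points ``at``."""
    x = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(x, np.asarray(at, dtype=float), side="right") / len(x)


@dataclass
class MetricSummary:
    n: int
    mean: float
    median: float
    sem: Optional[float]  # s / sqrt(n); None when n == 1
    median_se_bootstrap: Optional[float]
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    ecdf_x: np.ndarray
    ecdf_p: np.ndarray
    values: np.ndarray  # raw sample, kept for two-sample tests


@dataclass
class ConditionSummary:
    condition: str
    n_tracks: int
    metrics: dict[str, MetricSummary]
    class_fractions: dict[str, float]


DEFAULT_METRICS = ("length", "displacement", "straightness", "mean_speed")


def _freedman_diaconis_bins(x: np.ndarray) -> np.ndarray:
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0 or len(x) < 2 or np.ptp(x) == 0:
        return np.histogram_bin_edges(x, bins=10)
    width = 2 * iqr / len(x) ** (1 / 3)
    n_bins = max(1, int(math.ceil(np.ptp(x) / width)))
    return np.histogram_bin_edges(x, bins=min(n_bins, 1000))


def _bootstrap_median_se(x: np.ndarray, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(x, size=(n_boot, len(x)), replace=True), axis=1
    )
    return float(meds.std(ddof=1))


def summarize_condition(
    metrics_table: pd.DataFrame,
    labels_table: Optional[pd.DataFrame],
    condition: str,
    metric_columns: Sequence[str] = DEFAULT_METRICS,
    bins: str | int = "fd",
    bootstrap_resamples: int = 1000,
    seed: int = 0,
) -> ConditionSummary:
    """Summarize one condition from a metrics table (+ optional labels).

    Tables are keyed by track_id. Per metric: mean, median, SEM = s/sqrt(n)
    (missing when n = 1), a seeded bootstrap SE of the median, a histogram
    (Freedman-Diaconis by default) and the ECDF. Class fractions come from
    the labels table when given.
    """
    sub = metrics_table[metrics_table["condition"] == condition]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no tracks for condition {condition!r}")

    out: dict[str, MetricSummary] = {}
    for col in metric_columns:
        x = sub[col].to_numpy(dtype=float)
        if bins == "fd":
            edges = _freedman_diaconis_bins(x)
        else:
            edges = np.histogram_bin_edges(x, bins=bins)
        counts, edges = np.histogram(x, bins=edges)
        ex, ep = ecdf(x)
        sem = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        med_se = (
            _bootstrap_median_se(x, bootstrap_resamples, seed) if n > 1 else None
        )
        out[col] = MetricSummary(
            n=n, mean=float(x.mean()), median=float(np.median(x)),
            sem=sem, median_se_bootstrap=med_se,
            hist_edges=edges, hist_counts=counts,
            ecdf_x=ex, ecdf_p=ep, values=x,
        )

    fractions: dict[str, float] = {}
    if labels_table is not None:
        lab = labels_table[labels_table["condition"] == condition]
        if len(lab):
            counts_ = lab["label"].value_counts()
            fractions = {l: counts_.get(l, 0) / len(lab) for l in
                         ("immobile", "random", "directed", "caged", "complex")}
    return ConditionSummary(
        condition=condition, n_tracks=n, metrics=out, class_fractions=fractions
    )


def compare_conditions(
    summary_a: ConditionSummary,
    summary_b: ConditionSummary,
    metric: str,
    test: str = "ks",
) -> tuple[float, float]:
    """Two-sample two-sided test on one metric; returns (statistic, p).

    ``test="t"`` is Student's t-test; ``test="ks"`` is the two-sample
    Kolmogorov-Smirnov test whose statistic D is the maximum gap between
    the two ECDFs (computed from this package's own ECDFs, p-value from
    scipy's exact two-sample distribution).
    """
    if metric not in summary_a.metrics or metric not in summary_b.metrics:
        raise ValueError(f"metric {metric!r} missing from one of the summaries")
    a = summary_a.metrics[metric].values
    b = summary_b.metrics[metric].values
    if test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs >= 2 samples per side")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "ks":
        grid = np.concatenate([a, b])
        d = float(np.max(np.abs(ecdf_eval(a, grid) - ecdf_eval(b, grid))))
        p = float(stats.ks_2samp(a, b, method="auto").pvalue)
        return d, p
    raise ValueError(f"unknown test {test!r}; expected 't' or 'ks'")


def fraction_bars(labels_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-condition motion-class fractions with n, one row per condition."""
    if not labels_tables:
        raise ValueError("no label tables given")
    classes = ("immobile", "random", "directed", "caged", "complex")
    rows = []
    for cond, table in labels_tables.items():
        if len(table) == 0:
            raise ValueError(f"empty label table for condition {cond!r}")
        counts = table["label"].value_counts()
        row = {"condition": cond, "n": len(table)}
        for c in classes:
            row[c] = counts.get(c, 0) / len(table)
        rows.append(row)
    return pd.DataFrame(rows, columns=["condition", "n", *classes])


def plot_condition_summary(summary: ConditionSummary, metric: str, out_path):
    """Histogram + cumulative probability figure for one metric (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ms = summary.metrics[metric]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.stairs(ms.hist_counts, ms.hist_edges, fill=True)
    ax1.set_xlabel(metric)
    ax1.set_ylabel("count")
    ax2.step(ms.ecdf_x, ms.ecdf_p, where="post")
    ax2.set_xlabel(metric)
    ax2.set_ylabel("cumulative probability")
    ax2.set_ylim(0, 1.02)
    fig.suptitle(f"{summary.condition} (n={summary.n_tracks})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
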