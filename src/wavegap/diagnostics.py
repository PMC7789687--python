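"""Diagnostic accuracy of imputed values against held-out truth.

Per-imputation 2x2 confusion counts and the derived prevalence,
sensitivity, specificity, PPV and NPV (all in percent), pooled across the
m imputed datasets by averaging, with across-imputation intervals (2.5th
to 97.5th percentile by default; min-max also available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "DiagStats",
    "DiagnosticSummary",
    "confusion",
    "diag_stats",
    "pool_diagnostics",
    "round_half_up",
]

STAT_NAMES = ("prevalence", "sensitivity", "specificity", "ppv", "npv")
COUNT_NAMES = ("tn", "tp", "fn", "fp")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in COUNT_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(imputed, truth) -> ConfusionCounts:
    """2x2 tabulation of an imputed binary vector against truth."""
    a = np.asarray(imputed)
    b = np.asarray(truth)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("imputed and truth must be equal-length vectors")
    if pd.isna(a).any() or pd.isna(b).any():
        raise ValueError("missing values are not allowed in evaluation vectors")
    a = a.astype(np.int64)
    b = b.astype(np.int64)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("evaluation vectors must be binary 0/1")
    tp = int(np.sum((a == 1) & (b == 1)))
    fp = int(np.sum((a == 1) & (b == 0)))
    tn = int(np.sum((a == 0) & (b == 0)))
    fn = int(np.sum((a == 0) & (b == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class DiagStats:
    """The five headline statistics, in percent; NaN where undefined."""

    prevalence: float          # of the imputed series, 100 (tp+fp)/n
    truth_prevalence: float    # 100 (tp+fn)/n
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple = ()


def diag_stats(c: ConfusionCounts) -> DiagStats:
    """Prevalence, sensitivity, specificity, PPV and NPV in percent.

    A statistic whose denominator is zero is returned as NaN and flagged
    in ``undefined`` rather than silently zeroed.
    """
    n = c.n
    if n == 0:
        raise ValueError("empty confusion table")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    out = DiagStats(
        prevalence=100.0 * (c.tp + c.fp) / n,
        truth_prevalence=100.0 * (c.tp + c.fn) / n,
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        ppv=ratio(c.tp, c.tp + c.fp, "ppv"),
        npv=ratio(c.tn, c.tn + c.fn, "npv"),
        undefined=tuple(undefined),
    )
    return out


@dataclass
class DiagnosticSummary:
    """Across-imputation pooled diagnostics for one model.

    ``stats`` maps each statistic to (pooled mean, (lo, hi) percentile
    interval, (min, max)); ``counts`` the same for the four cells of the
    confusion table.  ``m`` is the number of imputed datasets.
    """

    stats: dict
    counts: dict
    n: int
    m: int

    def pooled(self, name: str) -> float:
        return self.stats[name][0]

    def interval(self, name: str) -> tuple:
        return self.stats[name][1]


def pool_diagnostics(per_dataset: list, interval: str = "percentile") -> DiagnosticSummary:
    """Pool per-imputation confusion counts across m datasets.

    ``per_dataset`` is a list of :class:`ConfusionCounts`, one per imputed
    dataset.  The pooled value of each statistic is the arithmetic mean of
    the per-dataset values; the across-imputation interval is the
    2.5th-97.5th percentile (``interval="percentile"``) or the min-max
    (``interval="minmax"``); both are stored.
    """
    if len(per_dataset) < 2:
        raise ValueError("pooling requires at least 2 imputed datasets")
    if interval not in ("percentile", "minmax"):
        raise ValueError("interval must be 'percentile' or 'minmax'")
    ns = {c.n for c in per_dataset}
    if len(ns) != 1:
        raise ValueError("confusion tables have differing totals")
    n = ns.pop()

    per_stats = [diag_stats(c) for c in per_dataset]

    def summarize(values):
        v = np.asarray(values, dtype=float)
        pct = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        mm = (float(v.min()), float(v.max()))
        return (float(v.mean()), pct if interval == "percentile" else mm,
                mm if interval == "percentile" else pct)

    stats = {name: summarize([getattr(s, name) for s in per_stats]) for name in STAT_NAMES}
    counts = {name: summarize([getattr(c, name) for c in per_dataset]) for name in COUNT_NAMES}
    return DiagnosticSummary(stats=stats, counts=counts, n=n, m=len(per_dataset))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero, as in printed reports."""
    if math.isnan(x):
        return x
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def diagnostics_report(summaries: dict, truth_counts: ConfusionCounts | None = None) -> pd.DataFrame:
    """Report table: rows = counts and statistics, columns = models.

    Counts are rounded to integers; sensitivity/specificity/PPV/NPV to
    integer percent; prevalence to two decimals — the precision of the
    printed diagnostic table this report mirrors.  Intervals are shown in
    parentheses.
    """
    rows = list(COUNT_NAMES) + list(STAT_NAMES)
    data = {}
    for model, summ in summaries.items():
        col = {}
        for name in COUNT_NAMES:
            mean, (lo, hi), _ = summ.counts[name]
            col[name] = f"{round_half_up(mean):.0f} ({round_half_up(lo):.0f}-{round_half_up(hi):.0f})"
        for name in STAT_NAMES:
            mean, (lo, hi), _ = summ.stats[name]
            d = 2 if name == "prevalence" else 0
            col[name] = (
                f"{round_half_up(mean, d):.{d}f} "
                f"({round_half_up(lo, d):.{d}f}-{round_half_up(hi, d):.{d}f})"
            )
        data[model] = col
    return pd.DataFrame(data, index=rows)
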