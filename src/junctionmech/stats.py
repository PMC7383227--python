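"""Nonparametric group statistics and box-plot summaries.

The quantifications produced by the imaging modules (per-cell FRET
efficiencies, per-island strain energy densities, per-field disruption
counts) are compared with rank-based tests: Kruskal-Wallis across multiple
groups, Wilcoxon rank-sum between two groups, and the Wilcoxon signed-rank
test against a fixed standard (1.0) for fold-of-control values.  Exact
p-values are used for small samples (combined n <= 25), a normal
approximation with continuity/tie correction otherwise.  All p-values are
two-sided.  Quantiles follow the linear-interpolation (type-7) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "GroupSummary",
    "SummaryRecord",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "signed_rank_vs_standard",
    "boxplot_summary",
]

EXACT_MAX_N = 25


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class SummaryRecord:
    """Result of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    groups: list[GroupSummary] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _summaries(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    out = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise DataError(f"group {name!r} is empty")
        if not np.all(np.isfinite(v)):
            raise DataError(f"group {name!r} contains non-finite values")
        out.append(GroupSummary(group=str(name), n=int(v.size),
                                median=float(np.median(v)),
                                q1=float(np.quantile(v, 0.25)),
                                q3=float(np.quantile(v, 0.75))))
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> SummaryRecord:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups.

    Degenerate data (all values identical) produce H = 0, p = 1 with a
    warning instead of an error.
    """
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    summaries = _summaries(groups)
    if any(s.n < 2 for s in summaries):
        raise DataError("each group needs n >= 2")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    record = SummaryRecord(test="kruskal_wallis", statistic=0.0, p_value=1.0,
                           groups=summaries)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        msg = "all values identical; H test degenerate (p = 1)"
        warnings.warn(msg)
        record.warnings.append(msg)
        return record
    h, p = sps.kruskal(*arrays)
    record.statistic = float(h)
    record.p_value = float(p)
    return record


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> SummaryRecord:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for combined n <= 25 and untied data; otherwise
    the normal approximation with continuity correction.  The reported
    statistic is the rank sum W of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs n >= 2")
    summaries = _summaries({"a": a, "b": b})
    record = SummaryRecord(test="wilcoxon_rank_sum", statistic=0.0,
                           p_value=1.0, groups=summaries)
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        msg = "all values identical; rank-sum degenerate (p = 1)"
        warnings.warn(msg)
        record.warnings.append(msg)
        record.statistic = float(a.size * (a.size + 1) / 2
                                 + a.size * b.size / 2)
        return record
    method = ("exact" if (a.size + b.size) <= EXACT_MAX_N and not ties
              else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2)  # U -> rank sum
    record.statistic = w
    record.p_value = float(res.pvalue)
    record.warnings += ([] if method == "exact" else
                        ["normal approximation with continuity correction"])
    return record


def signed_rank_vs_standard(folds: Sequence[float],
                            standard: float = 1.0) -> SummaryRecord:
    """Wilcoxon signed-rank test of normalized values against a standard.

    Zero differences are dropped (Wilcoxon convention).  Exact p for n <= 25
    untied differences, normal approximation otherwise.
    """
    folds = np.asarray(folds, dtype=float)
    if folds.size < 2:
        raise DataError("need n >= 2 values")
    summaries = _summaries({"folds": folds})
    record = SummaryRecord(test="wilcoxon_signed_rank", statistic=0.0,
                           p_value=1.0, groups=summaries)
    diffs = folds - standard
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        msg = f"all values equal the standard {standard}; test degenerate"
        warnings.warn(msg)
        record.warnings.append(msg)
        return record
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if nonzero.size <= EXACT_MAX_N and not ties else "approx"
    res = sps.wilcoxon(nonzero, zero_method="wilcox",
                       alternative="two-sided", method=method,
                       correction=(method == "approx"))
    record.statistic = float(res.statistic)
    record.p_value = float(res.pvalue)
    if method != "exact":
        record.warnings.append("normal approximation (large n or ties)")
    return record


def boxplot_summary(groups: Mapping[str, Sequence[float]],
                    show_points: bool = True,
                    ylabel: str = "") -> tuple[list[GroupSummary], object]:
    """Median/quartile summaries plus a box plot with overlaid data points.

    Boxes span the 25th to 75th percentiles with a line at the median
    (linear-interpolation quantiles); individual data points are overlaid
    when ``show_points`` is set.  Returns (summaries, matplotlib Figure).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summaries = _summaries(groups)
    fig, ax = plt.subplots(figsize=(1.2 * max(len(groups), 2) + 1, 4))
    names = [s.group for s in summaries]
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    ax.boxplot(data, tick_labels=names, whis=(0, 100), showfliers=False)
    if show_points:
        rng = np.random.default_rng(0)  # jitter only, cosmetic
        for i, vals in enumerate(data, start=1):
            x = i + rng.uniform(-0.12, 0.12, size=len(vals))
            ax.plot(x, vals, "o", ms=3, alpha=0.6, color="k")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return summaries, fig
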