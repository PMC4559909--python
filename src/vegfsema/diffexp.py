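"""Per-gene two-group tests, BH correction, and cross-dataset recurrence.

The cross-dataset analysis asks, per gene and tissue contrast, whether a
change is *recurrent*: significant (q < alpha) in the same direction in at
least two datasets with no significant difference in any other dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ExpressionMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"

FLAG_RECURRENT_UP = "recurrent_up"
FLAG_RECURRENT_DOWN = "recurrent_down"
FLAG_NONE = "none"


def welch_t_two_tailed(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of x vs y, two-tailed.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    The degenerate all-constant, equal-means case returns ``(0, df, 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pooled_t_two_tailed(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Student's pooled-variance t-test (alternative to Welch, by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the ascending order, capped
    at 1, returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_groups(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-gene t-tests of group_b vs group_a with BH correction.

    Returns a genes-indexed table with ``mean_diff`` (b minus a, log2),
    ``t_stat``, ``df``, ``p``, ``q`` and ``direction`` (up/down/none; set by
    the sign of mean_diff when q < alpha).  BH is applied across the panel
    genes within this single comparison.
    """
    a = m.group_values(group_a).to_numpy()
    b = m.group_values(group_b).to_numpy()
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(f"groups {group_a!r}/{group_b!r} need >= 2 samples each")
    test = welch_t_two_tailed if welch else pooled_t_two_tailed
    rows = []
    for j, gene in enumerate(m.gene_symbols):
        t, df, p = test(b[:, j], a[:, j])
        rows.append((gene, float(b[:, j].mean() - a[:, j].mean()), t, df, p))
    tab = pd.DataFrame(rows, columns=["gene", "mean_diff", "t_stat", "df", "p"]
                       ).set_index("gene")
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    sig = tab["q"] < alpha
    tab["direction"] = np.where(~sig, DIRECTION_NONE,
                                np.where(tab["mean_diff"] > 0, DIRECTION_UP, DIRECTION_DOWN))
    tab.attrs["comparison"] = f"{group_b}_vs_{group_a}"
    tab.attrs["alpha"] = alpha
    return tab


def recurrence_summary(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-dataset recurrence flags from per-dataset comparison tables.

    A gene is ``recurrent_down`` when it is significantly down in two or
    more datasets and significant in no other dataset in either direction;
    symmetrically for ``recurrent_up``.
    """
    if len(results) < 2:
        raise ValueError("need comparison tables from at least 2 datasets")
    genes = results[0].index
    for tab in results[1:]:
        if not tab.index.equals(genes):
            raise ValueError("mismatched gene sets across datasets")
    n_up = sum((tab["direction"] == DIRECTION_UP).astype(int) for tab in results)
    n_down = sum((tab["direction"] == DIRECTION_DOWN).astype(int) for tab in results)
    flag = np.full(len(genes), FLAG_NONE, dtype=object)
    flag[(n_down >= 2) & (n_up == 0)] = FLAG_RECURRENT_DOWN
    flag[(n_up >= 2) & (n_down == 0)] = FLAG_RECURRENT_UP
    return pd.DataFrame({
        "n_sig_up": n_up.astype(int),
        "n_sig_down": n_down.astype(int),
        "n_datasets_tested": len(results),
        "flag": flag,
    }, index=genes)


@dataclass
class DistributionSummary:
    """Kernel density plus box-plot statistics for one gene/group."""

    grid: np.ndarray
    density: np.ndarray
    median: float
    q1: float
    q3: float
    points: np.ndarray


def distribution_summary(values: np.ndarray, n_grid: int = 512) -> DistributionSummary:
    """Gaussian KDE (Silverman bandwidth) plus quartiles of one sample.

    Quartiles use the linear-interpolation convention (numpy default), the
    one under which the quartiles of 1..8 are 2.75 and 6.25.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 finite values")
    if v.var() == 0.0:
        raise ValueError("zero-variance sample: kernel bandwidth degenerate")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(v.min() - 4 * bw, v.max() + 4 * bw, n_grid)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return DistributionSummary(grid=grid, density=kde(grid), median=float(med),
                               q1=float(q1), q3=float(q3), points=v)
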