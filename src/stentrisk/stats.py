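"""Baseline-comparison statistics for cohort splits.

Implements the Table-1 toolchain: pooled-variance two-sample *t* from
summary statistics, uncorrected Pearson chi-square on 2 x k contingency
tables, Mann-Whitney U with mid-rank ties, and the dispatcher that builds a
train-vs-test baseline comparison table. Normal-vs-skewed dispatch for
continuous variables uses a Shapiro-Wilk gate at alpha = 0.05 per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schema import OUTCOME, CohortTable
from .split import SplitResult

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class SummaryStats:
    """Group summary for one variable, matching its kind's convention."""

    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    level_counts: dict | None = None


@dataclass(frozen=True)
class BaselineComparison:
    variable: str
    test: str  # pooled_t | mann_whitney_u | pearson_chi2
    statistic: float
    p_value: float


def pooled_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Student (pooled-variance) two-sample t from group summaries.

    Returns ``(|t|, p)`` with the two-tailed p on ``n1 + n2 - 2`` degrees of
    freedom. The absolute statistic is reported, matching the convention of
    baseline-characteristics tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = abs(mean1 - mean2)
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: infinite statistic")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(t, df)
    return float(t), float(p)


def pearson_chi2(counts) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2 x k contingency table."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = row * col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return chi2, p


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (mid-rank ties); reports the smaller orientation.

    p is exact for small untied samples (min(n) <= 8), otherwise from the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(min(res.statistic, len(x) * len(y) - res.statistic))
    return u, float(res.pvalue)


def summarize(values, kind: str, categories=None) -> SummaryStats:
    """Summary in the convention of the variable's kind."""
    if kind in ("binary", "categorical"):
        s = pd.Series(values)
        if kind == "binary":
            counts = {int(k): int(v) for k, v in s.value_counts().items()}
        else:
            counts = {c: int((s == c).sum()) for c in (categories or s.unique())}
        return SummaryStats(n=len(s), level_counts=counts)
    v = np.asarray(values, dtype=float)
    if kind == "continuous_normal":
        return SummaryStats(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SummaryStats(n=len(v), median=float(med), q1=float(q1), q3=float(q3))


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    # Shapiro-Wilk is limited to n <= 5000 in older scipy; cohorts here are smaller.
    return sps.shapiro(values).pvalue > SHAPIRO_ALPHA


def baseline_table(table: CohortTable, split: SplitResult) -> list[BaselineComparison]:
    """Train-vs-test comparison, one row per variable plus the outcome.

    Continuous variables are compared with the pooled t-test when both
    groups pass Shapiro-Wilk normality at alpha = 0.05, otherwise with the
    Mann-Whitney U test; binary/categorical variables (and the outcome) use
    the uncorrected Pearson chi-square. A constant variable is reported as
    statistic 0, p 1.
    """
    tr = np.asarray(sorted(split.train_index), dtype=int)
    te = np.asarray(sorted(split.test_index), dtype=int)
    if len(np.intersect1d(tr, te)) or len(tr) + len(te) != len(table):
        raise ValueError("split does not partition the table")

    rows: list[BaselineComparison] = []

    def chi2_row(name: str, a: pd.Series, b: pd.Series, levels) -> BaselineComparison:
        counts = np.array(
            [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
        )
        keep = counts.sum(axis=0) > 0
        counts = counts[:, keep]
        if counts.shape[1] < 2:
            return BaselineComparison(name, "pearson_chi2", 0.0, 1.0)
        chi2, p = pearson_chi2(counts)
        return BaselineComparison(name, "pearson_chi2", chi2, p)

    y = pd.Series(table.outcome)
    rows.append(chi2_row(OUTCOME, y.iloc[tr], y.iloc[te], [1, 0]))

    for var in table.schema:
        col = table.records[var.name]
        a, b = col.iloc[tr], col.iloc[te]
        if var.kind == "binary":
            rows.append(chi2_row(var.name, a, b, [1, 0]))
        elif var.kind == "categorical":
            rows.append(chi2_row(var.name, a, b, list(var.categories)))
        else:
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            if np.ptp(np.concatenate([av, bv])) == 0:
                rows.append(BaselineComparison(var.name, "pooled_t", 0.0, 1.0))
                continue
            use_t = (
                var.kind == "continuous_normal"
                and _is_normal(av)
                and _is_normal(bv)
            )
            if use_t:
                t, p = pooled_t_from_summary(
                    len(av), av.mean(), av.std(ddof=1), len(bv), bv.mean(), bv.std(ddof=1)
                )
                rows.append(BaselineComparison(var.name, "pooled_t", t, p))
            else:
                u, p = mann_whitney_u(av, bv)
                rows.append(BaselineComparison(var.name, "mann_whitney_u", u, p))
    return rows


def baseline_frame(rows: list[BaselineComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
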