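"""Small statistical utilities for cohort comparisons.

These reproduce the demographic comparisons reported alongside the genomic
analysis: pooled two-sample t tests computed from printed summary statistics
(mean, SD, n per group) and Pearson chi-square tests on 2x2 proportion
tables, plus the Bonferroni threshold helper used by the variant follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "pooled_t_from_summary",
    "two_proportion_chisq",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p_value: float


def pooled_t_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> TTestResult:
    """Equal-variance two-sample t from per-group summary statistics."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * _st.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def two_proportion_chisq(x1: int, n1: int, x2: int, n2: int) -> ChisqResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    if min(n1, n2) <= 0 or not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("invalid counts")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    chi2, p, _, _ = _st.chi2_contingency(table, correction=False)
    return ChisqResult(float(chi2), 1, float(p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m
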