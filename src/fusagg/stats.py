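"""Shared statistics: replicate summaries, Welch's t-test and the
significance-star annotation used in all reporting paths.

The Welch statistic is assembled explicitly from the textbook formulas
(unequal-variance two-sample t with Welch-Satterthwaite degrees of
freedom); only the t distribution's CDF comes from scipy. Tests are
two-sided throughout. A pooled-variance Student mode is available where
group variances are known to be comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

__all__ = ["GroupSummary", "TTestResult", "welch_t_test", "student_t_test", "significance_stars", "summarize_group"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def summarize_group(label: str, values) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)


def welch_t_test(a, b) -> TTestResult:
    """Two-sided Welch (unequal-variance) two-sample t-test.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite df. Degenerate case: both groups with zero variance
    and equal means gives p = 1 (no evidence of difference); zero variance
    with unequal means gives p = 0 in the limit, reported as the smallest
    positive float to keep p in (0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    ma, mb = float(a.mean()), float(b.mean())
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        if ma == mb:
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p_value=1.0)
        return TTestResult(t=math.inf if ma > mb else -math.inf,
                           df=float(a.size + b.size - 2),
                           p_value=math.nextafter(0.0, 1.0))
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(t=t, df=df, p_value=min(max(p, math.nextafter(0.0, 1.0)), 1.0))


def student_t_test(a, b) -> TTestResult:
    """Two-sided pooled-variance Student t-test (config alternative)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se2 = sp2 * (1.0 / a.size + 1.0 / b.size)
    if se2 == 0.0:
        if float(a.mean()) == float(b.mean()):
            return TTestResult(t=0.0, df=float(df), p_value=1.0)
        return TTestResult(t=math.inf if a.mean() > b.mean() else -math.inf,
                           df=float(df), p_value=math.nextafter(0.0, 1.0))
    t = (float(a.mean()) - float(b.mean())) / math.sqrt(se2)
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p_value=min(max(p, math.nextafter(0.0, 1.0)), 1.0))


def significance_stars(p_value: float) -> str:
    """Figure-legend annotation: ``***`` p < 0.001, ``**`` p < 0.01,
    ``*`` p < 0.05, else ``n.s.``. Boundaries are strict (p = 0.05 is n.s.)."""
    if not (0.0 < p_value <= 1.0):
        raise ValueError(f"p-value must be in (0, 1], got {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "n.s."
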