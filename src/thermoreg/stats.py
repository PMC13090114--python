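"""Inferential tests used by the pipeline: Welch t, TOST equivalence,
Kruskal–Wallis.

Welch's unequal-variance t is used as the base two-sample test throughout,
including inside the TOST procedure.  TOST (two one-sided tests) declares
statistical equivalence of two samples when the mean difference is
significantly above -margin AND significantly below +margin; its null
hypothesis is that the samples differ by more than the margin.
Kruskal–Wallis uses midranks with tie correction and the chi-square
approximation with k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.weightstats import ttost_ind

from .errors import DataError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    test: str
    degenerate: bool = False


@dataclass(frozen=True)
class TostResult:
    """Two one-sided tests against ±margin with an equivalence verdict."""

    margin: float
    mean_diff: float
    p_lower: float  # H0: diff <= -margin  vs  H1: diff > -margin
    p_upper: float  # H0: diff >= +margin  vs  H1: diff < +margin
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def equivalent(self) -> bool:
        return self.p_lower < self.alpha and self.p_upper < self.alpha


def _as_sample(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 2:
        raise DataError(f"sample {name} needs >= 2 values, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise DataError(f"sample {name} contains non-finite values")
    return a


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Degenerate inputs (both samples constant) return t = 0, p = 1 when the
    means agree and t = ±inf, p = 0 otherwise, flagged as degenerate.
    """
    a, b = _as_sample(x, "x"), _as_sample(y, "y")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "welch_t", True)
        return TestResult(
            float(np.sign(diff)) * np.inf, float(a.size + b.size - 2), 0.0,
            "welch_t", True,
        )
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def tost(x, y, margin: float, alpha: float = 0.05) -> TostResult:
    """Equivalence of two sample means within ±margin via two one-sided
    Welch tests.  ``equivalent`` iff both one-sided p-values are < alpha.
    """
    if not margin > 0:
        raise DataError(f"margin must be positive, got {margin}")
    a, b = _as_sample(x, "x"), _as_sample(y, "y")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # Point masses: the verdict follows directly from the difference.
        inside = abs(diff) < margin
        p = 0.0 if inside else 1.0
        return TostResult(margin, diff, p, p, alpha, degenerate=True)
    _, (t1, p_lower, _), (t2, p_upper, _) = ttost_ind(
        a, b, -margin, margin, usevar="unequal"
    )
    return TostResult(margin, diff, float(p_lower), float(p_upper), alpha)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H across >= 2 groups, chi-square p with k-1 df.

    All observations identical yields H = 0, p = 1 (flagged degenerate)
    rather than an error.
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise DataError(f"need >= 2 groups, got {len(gs)}")
    total = sum(g.size for g in gs)
    if total < 3:
        raise DataError(f"need >= 3 observations in total, got {total}")
    if any(g.size == 0 for g in gs):
        raise DataError("empty group")
    df = float(len(gs) - 1)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, df, 1.0, "kruskal_wallis", True)
    res = scipy.stats.kruskal(*gs)
    return TestResult(float(res.statistic), df, float(res.pvalue), "kruskal_wallis")
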