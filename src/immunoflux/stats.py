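"""Shared statistical primitives used by every analysis arm.

Two-sample location tests (Welch and pooled-variance Student, both
two-tailed), Benjamini–Hochberg step-up FDR control, and two-sided
standard-normal tail probabilities.  Group order is fixed everywhere:
the test statistic carries the sign of ``mean(a) - mean(b)``, so swapping
the groups negates the statistic and leaves the p-value unchanged.

Degenerate inputs (no variance anywhere, fewer than two observations)
raise typed errors instead of propagating NaN, so pipeline stages fail
loudly rather than silently producing unusable tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "welch_ttest",
    "student_ttest",
    "bh_fdr",
    "normal_ztest_p",
]


class DegenerateDataError(ValueError):
    """Raised when a test cannot be formed (e.g. zero variance in both groups)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison.

    ``statistic`` has the sign of ``mean_a - mean_b``; ``p_value`` is
    two-tailed.  ``df`` is the Welch–Satterthwaite df for Welch's test and
    ``n_a + n_b - 2`` for Student's.
    """

    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _as_group(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"group {name!r} needs >= 2 observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def welch_ttest(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-tailed).

    Uses the Welch–Satterthwaite degrees of freedom.  If both groups have
    zero variance the t statistic is undefined and a
    :class:`DegenerateDataError` is raised (equal or unequal means alike:
    with no variance the sampling model collapses).
    """
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            raise DegenerateDataError("both groups constant with equal means")
        raise DegenerateDataError("both groups constant; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def student_ttest(a, b) -> TestResult:
    """Pooled-variance Student two-sample t-test (two-tailed), df = n_a+n_b-2."""
    a = _as_group(a, "a")
    b = _as_group(b, "b")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            raise DegenerateDataError("zero pooled variance with equal means")
        raise DegenerateDataError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(a.size + b.size - 2),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Returned in the input order.  Each q is ``min over j with p_(j) >= p_(i)
    of p_(j) * m / j`` capped at 1, the standard monotone step-up adjustment.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def normal_ztest_p(z: float) -> float:
    """Two-sided standard-normal tail probability, 2*P(|Z| >= |z|)."""
    z = float(z)
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))
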