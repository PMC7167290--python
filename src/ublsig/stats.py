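"""Hypothesis tests used throughout the array and bead analyses.

The modification- and differential-calling steps rely on a small set of
classical tests: Welch's unequal-variance t test, the one-sample and paired
t tests, the Wilcoxon-Mann-Whitney rank-sum test and the Wilcoxon
signed-rank test.  They are implemented here from first principles so that
the exact small-sample branches (full null distributions, not normal
approximations) are available and independently verifiable.

All tests are two-sided by default, matching how they gate the calling
procedures.  Degenerate inputs follow explicit conventions: zero variance
with equal locations gives p = 1, zero variance with distinct locations
gives p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import rankdata

__all__ = ["TestResult", "t_test", "mann_whitney_u", "wilcoxon_signed_rank"]

# Largest pooled / single sample size for which the exact null distribution
# is enumerated rather than approximated.  Sub-second on one core.
EXACT_MWU_MAX_N = 16
EXACT_SIGNRANK_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (t, U, or W+ depending on the method).
    df : float or None
        Degrees of freedom where defined (t tests only).
    p_value : float
        Two-sided p-value in [0, 1] unless another sidedness was requested.
    sided : str
        ``"two-sided"``, ``"greater"`` or ``"less"``.
    method : str
        Tag identifying the test and branch, e.g. ``"mann_whitney_u/exact"``.
    n : tuple[int, ...]
        Per-group sample sizes actually used.
    """

    statistic: float
    df: float | None
    p_value: float
    sided: str
    method: str
    n: tuple[int, ...]


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _t_sf(t: float, df: float) -> float:
    """Upper tail of Student's t via the regularized incomplete beta."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def _finish_t(stat: float, df: float, sided: str, method: str,
              n: tuple[int, ...]) -> TestResult:
    if math.isnan(stat):
        raise ValueError("undefined t statistic")
    sf = _t_sf(stat, df)
    if sided == "two-sided":
        p = min(1.0, 2.0 * min(sf, 1.0 - sf))
    elif sided == "greater":
        p = sf
    elif sided == "less":
        p = 1.0 - sf
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return TestResult(stat, df, p, sided, method, n)


def t_test(x, y_or_mu=0.0, mode: str = "welch_two_sample",
           sided: str = "two-sided") -> TestResult:
    """t test in one of three modes.

    ``welch_two_sample``
        Unequal-variance two-sample test with Welch-Satterthwaite degrees
        of freedom.  ``y_or_mu`` is the second sample.
    ``one_sample``
        Tests mean(x) against the scalar ``y_or_mu``.
    ``paired``
        ``y_or_mu`` is a paired sample; reduces to a one-sample test on the
        element-wise differences against 0.

    Zero-variance conventions: if every observation equals the null
    location the statistic is 0 and p = 1; if the variance is zero but the
    locations differ, p = 0 (the data are incompatible with the null with
    certainty under the model).
    """
    x = _as_array(x, "x")
    if mode == "welch_two_sample":
        y = _as_array(y_or_mu, "y")
        if x.size < 2 or y.size < 2:
            raise ValueError("welch t test needs at least 2 values per group")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        delta = x.mean() - y.mean()
        if vx == 0.0 and vy == 0.0:
            p = 1.0 if delta == 0.0 else 0.0
            stat = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
            return TestResult(stat, float(x.size + y.size - 2), p, sided,
                              "t_test/welch_two_sample", (x.size, y.size))
        se2 = vx / x.size + vy / y.size
        stat = delta / math.sqrt(se2)
        df = se2 ** 2 / ((vx / x.size) ** 2 / (x.size - 1)
                         + (vy / y.size) ** 2 / (y.size - 1))
        return _finish_t(stat, df, sided, "t_test/welch_two_sample",
                         (x.size, y.size))
    if mode == "paired":
        y = _as_array(y_or_mu, "y")
        if x.size != y.size:
            raise ValueError("paired t test needs equal-length samples")
        res = t_test(x - y, 0.0, mode="one_sample", sided=sided)
        return TestResult(res.statistic, res.df, res.p_value, sided,
                          "t_test/paired", (x.size,))
    if mode == "one_sample":
        mu = float(np.asarray(y_or_mu).item())
        if x.size < 2:
            raise ValueError("one-sample t test needs at least 2 values")
        v = x.var(ddof=1)
        delta = x.mean() - mu
        if v == 0.0:
            p = 1.0 if delta == 0.0 else 0.0
            stat = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
            return TestResult(stat, float(x.size - 1), p, sided,
                              "t_test/one_sample", (x.size,))
        stat = delta / math.sqrt(v / x.size)
        return _finish_t(stat, float(x.size - 1), sided,
                         "t_test/one_sample", (x.size,))
    raise ValueError(f"unknown t test mode {mode!r}")


def _mwu_exact_counts(n: int, m: int) -> np.ndarray:
    """Number of labelings of n+m ranks giving each value of U = 0..nm.

    Classic recurrence: counts[n][m][u] = counts[n-1][m][u-m] +
    counts[n][m-1][u], implemented as a rolling polynomial product; the
    result is the exact permutation distribution of U for tie-free data.
    """
    # f(i, j, u): the largest pooled rank is either an x (it beats all j
    # y's, contributing j to U) or a y, giving
    # f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u).
    size = n * m + 1
    prev = np.zeros((m + 1, size))   # i = 0
    prev[:, 0] = 1.0
    for i in range(1, n + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0              # j = 0
        for j in range(1, m + 1):
            cur[j] = cur[j - 1]
            cur[j, j:] += prev[j, : size - j]
        prev = cur
    return prev[m]


def mann_whitney_u(x, y, sided: str = "two-sided") -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    U counts pairs (x_i, y_j) with x_i > y_j (ties count 1/2).  The exact
    null distribution is used when n + m <= 16 and the pooled data are
    tie-free; otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("mann_whitney_u needs non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[:n].sum()
    u = rx - n * (n + 1) / 2.0  # = #{x>y} + 0.5 * #{x==y}
    has_ties = np.unique(pooled).size < pooled.size

    if n + m <= EXACT_MWU_MAX_N and not has_ties:
        counts = _mwu_exact_counts(n, m)
        total = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total  # includes the point mass
        if sided == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif sided == "greater":
            p = sf
        else:
            p = cdf
        return TestResult(u, None, p, sided, "mann_whitney_u/exact", (n, m))

    mean_u = n * m / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = (t_counts ** 3 - t_counts).sum()
    big_n = n + m
    var_u = n * m / 12.0 * (big_n + 1 - tie_term / (big_n * (big_n - 1)))
    if var_u <= 0.0:  # all pooled values identical
        return TestResult(u, None, 1.0, sided, "mann_whitney_u/approx", (n, m))
    sd = math.sqrt(var_u)
    if sided == "two-sided":
        z = (abs(u - mean_u) - 0.5) / sd
        p = min(1.0, 2.0 * special.ndtr(-max(z, 0.0)))
    elif sided == "greater":
        z = (u - mean_u - 0.5) / sd
        p = float(special.ndtr(-z))
    else:
        z = (u - mean_u + 0.5) / sd
        p = float(special.ndtr(z))
    return TestResult(u, None, p, sided, "mann_whitney_u/approx", (n, m))


def _signrank_exact_counts(ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ = sum of ranks of positive signs over all 2^n
    equiprobable sign assignments, by polynomial convolution."""
    max_w = int(round(ranks.sum()))
    c = np.zeros(max_w + 1, dtype=float)
    c[0] = 1.0
    for r in ranks:
        ri = int(round(r))
        shifted = np.zeros_like(c)
        shifted[ri:] = c[:max_w + 1 - ri]
        c = c + shifted
    return c


def wilcoxon_signed_rank(values, mu: float = 0.0,
                         sided: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test of symmetry of ``values`` about ``mu``.

    Observations exactly equal to ``mu`` are dropped before ranking
    (Wilcoxon's convention).  The exact 2^n null distribution of W+ is
    used when n <= 20 and the absolute deviations are tie-free; otherwise
    a normal approximation with tie and continuity corrections.
    """
    v = _as_array(values, "values") - float(mu)
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        # every observation sat exactly at mu
        return TestResult(0.0, None, 1.0, sided, "wilcoxon_signed_rank/degenerate", (0,))
    absv = np.abs(v)
    ranks = rankdata(absv)
    w_plus = ranks[v > 0].sum()
    has_ties = np.unique(absv).size < n

    if n <= EXACT_SIGNRANK_MAX_N and not has_ties:
        counts = _signrank_exact_counts(ranks)
        total = counts.sum()  # 2^n
        wi = int(round(w_plus))
        cdf = counts[: wi + 1].sum() / total
        sf = counts[wi:].sum() / total
        if sided == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif sided == "greater":
            p = sf
        else:
            p = cdf
        return TestResult(w_plus, None, p, sided,
                          "wilcoxon_signed_rank/exact", (n,))

    mean_w = n * (n + 1) / 4.0
    _, t_counts = np.unique(absv, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (t_counts ** 3 - t_counts).sum() / 48.0
    if var_w <= 0.0:
        return TestResult(w_plus, None, 1.0, sided,
                          "wilcoxon_signed_rank/approx", (n,))
    sd = math.sqrt(var_w)
    if sided == "two-sided":
        z = (abs(w_plus - mean_w) - 0.5) / sd
        p = min(1.0, 2.0 * special.ndtr(-max(z, 0.0)))
    elif sided == "greater":
        z = (w_plus - mean_w - 0.5) / sd
        p = float(special.ndtr(-z))
    else:
        z = (w_plus - mean_w + 0.5) / sd
        p = float(special.ndtr(z))
    return TestResult(w_plus, None, p, sided,
                      "wilcoxon_signed_rank/approx", (n,))
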