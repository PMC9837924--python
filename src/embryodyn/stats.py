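"""Statistical primitives used across the pipeline.

Fisher's exact test (hypergeometric enumeration over the table support),
Mann-Whitney U (exact rank-sum distribution for small untied samples, else a
tie- and continuity-corrected normal approximation), Pearson correlation with
the t-based p-value, Benjamini-Hochberg FDR, and a Welch-type two-sample test
on log2(x+1) used for replicate-level differential calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str = "two-sided"
    method: str = ""
    effect: float | None = None  # odds ratio / r / log2FC depending on test
    undefined: bool = False

    def __post_init__(self):
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


_ALTS = ("two-sided", "greater", "less")


def fisher_exact(a: int, b: int, c: int, d: int,
                 alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Conditions on the margins: the count in cell ``a`` follows a
    hypergeometric distribution.  The two-sided p-value sums the
    probabilities of all tables no more probable than the observed one
    (with a 1e-7 relative tolerance for floating-point ties).  ``effect``
    carries the sample odds ratio (``inf`` when b*c == 0 and a*d > 0).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if alternative not in _ALTS:
        raise ValueError(f"unknown alternative {alternative!r}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(statistic=float(odds), p_value=min(1.0, p),
                      alternative=alternative, method="fisher-exact",
                      effect=float(odds))


def _exact_u_sf(n1: int, n2: int) -> np.ndarray:
    """Counts of label assignments per U value, by dynamic programming.

    Returns an array ``cnt`` with ``cnt[u]`` = number of ways to choose which
    n1 of the n1+n2 ranks belong to sample x such that U(x) == u.
    """
    # f[k][u]: ways to pick k items from the first i ranks with rank-sum offset u
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for k in range(min(i, n1), 0, -1):
            # taking rank i as the k-th chosen element adds (i - k) to U
            add = i - k
            if add <= max_u:
                f[k, add:] += f[k - 1, : max_u + 1 - add]
    return f[n1]


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact when n1+n2 <= 12 with no ties; otherwise a normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative not in _ALTS:
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= 12 and not has_ties:
        cnt = _exact_u_sf(n1, n2)
        total = cnt.sum()
        u_int = int(round(u1))
        if alternative == "greater":
            p = cnt[u_int:].sum() / total
        elif alternative == "less":
            p = cnt[: u_int + 1].sum() / total
        else:
            tail = min(cnt[u_int:].sum(), cnt[: u_int + 1].sum())
            p = min(1.0, 2.0 * tail / total)
        method = "mann-whitney-exact"
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        nn = n1 + n2
        var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
        if var == 0:
            return TestResult(statistic=float(u1), p_value=1.0,
                              alternative=alternative,
                              method="mann-whitney-normal", undefined=True)
        sd = np.sqrt(var)
        if alternative == "greater":
            z = (u1 - mu - 0.5) / sd
            p = sps.norm.sf(z)
        elif alternative == "less":
            z = (u1 - mu + 0.5) / sd
            p = sps.norm.cdf(z)
        else:
            z = (abs(u1 - mu) - 0.5) / sd
            p = 2.0 * sps.norm.sf(z)
        p = float(min(1.0, max(0.0, p)))
        method = "mann-whitney-normal"
    return TestResult(statistic=float(u1), p_value=float(p),
                      alternative=alternative, method=method)


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with the t-distribution p-value.

    Zero-variance input yields a result flagged ``undefined=True`` with
    p_value 1.0 so that screening consumers drop the pair rather than crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_test needs two equal-length vectors, n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return TestResult(statistic=np.nan, p_value=1.0, method="pearson",
                          effect=np.nan, undefined=True)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(statistic=r, p_value=min(1.0, p), method="pearson",
                      effect=r)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def two_sample_log_test(group_a, group_b) -> TestResult:
    """Welch t-test on log2(value + 1); ``effect`` is the log2 fold change
    (mean of B minus mean of A on the log scale)."""
    a = np.log2(np.asarray(group_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(group_b, dtype=float) + 1.0)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    log2fc = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        p = 1.0 if log2fc == 0.0 else 0.0
        return TestResult(statistic=np.inf if log2fc else 0.0, p_value=p,
                          method="welch-log2", effect=log2fc)
    t = log2fc / np.sqrt(se2)
    df = se2 ** 2 / ((va / a.size) ** 2 / (a.size - 1)
                     + (vb / b.size) ** 2 / (b.size - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(1.0, p),
                      method="welch-log2", effect=log2fc)
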