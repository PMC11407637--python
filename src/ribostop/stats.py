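"""Shared statistical primitives for the figure-level comparisons.

Thin, uniformly shaped wrappers around scipy's tests plus a vectorized
Benjamini-Hochberg step-up. Every test returns a :class:`TestResult`;
families of tests are adjusted together with :func:`bh_adjust`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    comparison: str
    statistic: float
    pvalue: float
    method: str
    n: tuple[int, ...] = ()
    padj: float | None = None
    flags: tuple[str, ...] = ()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``padj_(i) = min_{j >= i} ( m * p_(j) / j )`` on the sorted p-values,
    capped at 1; ties share the adjusted value of their sorted position.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def attach_bh(results: list[TestResult]) -> list[TestResult]:
    """Adjust a family of TestResults in place (BH across the family)."""
    if results:
        padj = bh_adjust([r.pvalue for r in results])
        for r, a in zip(results, padj):
            r.padj = float(a)
    return results


def rank_sum_test(x, y, two_sided: bool = True, exact_max_n: int = 8) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    Uses the exact null distribution when ``min(n) <= exact_max_n`` and the
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections. All-tied data return p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 observations per group")
    alternative = "two-sided" if two_sided else "greater"
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(
            "x vs y", float(x.size * y.size / 2), 1.0, "rank-sum (all tied)",
            (x.size, y.size), flags=("all_tied",),
        )
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (min(x.size, y.size) <= exact_max_n) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(
        "x vs y", float(res.statistic), float(res.pvalue),
        f"rank-sum ({method})", (x.size, y.size),
    )


def pairwise_count_tests(
    tables: dict[str, np.ndarray], method: str = "fisher"
) -> list[TestResult]:
    """Fisher's exact (2x2) or chi-squared tests over a family of contingency
    tables, BH-adjusted across the family.

    ``tables`` maps a comparison label to a 2xk count table. Chi-squared
    tests with any expected count < 1 fall back to Fisher (2x2 only) with a
    note; larger sparse tables keep the chi-squared p with a flag.
    """
    results = []
    for label, table in tables.items():
        t = np.asarray(table)
        if np.any(t < 0):
            raise ValueError(f"{label}: negative counts")
        if method == "fisher" and t.shape == (2, 2):
            stat, p = sps.fisher_exact(t, alternative="two-sided")
            results.append(TestResult(label, float(stat), float(p), "fisher", (int(t[0].sum()), int(t[1].sum()))))
            continue
        chi2 = sps.chi2_contingency(t, correction=False)
        flags: tuple[str, ...] = ()
        if np.any(chi2.expected_freq < 1):
            if t.shape == (2, 2):
                stat, p = sps.fisher_exact(t, alternative="two-sided")
                results.append(TestResult(label, float(stat), float(p),
                                          "fisher (chi2 fallback)", (int(t[0].sum()), int(t[1].sum()))))
                continue
            flags = ("low_expected_counts",)
        results.append(TestResult(label, float(chi2.statistic), float(chi2.pvalue),
                                  "chi2", (int(t[0].sum()), int(t[1].sum())), flags=flags))
    return attach_bh(results)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n, any ties)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    obs = abs(rho_obs)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = float(rx @ ry[list(perm)]) / denom
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact_max_n: int = 8) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    p-value by exact permutation for ``n <= exact_max_n``, otherwise the
    t-approximation. Zero rank variance returns rho = nan with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult("spearman", float("nan"), float("nan"),
                          "spearman (degenerate)", (x.size,), flags=("zero_rank_variance",))
    rho, p = sps.spearmanr(x, y)
    method = "t-approx"
    if x.size <= exact_max_n:
        p = _spearman_exact_p(x, y, float(rho))
        method = "exact-permutation"
    return TestResult("spearman", float(rho), float(p), f"spearman ({method})", (x.size,))


def unpaired_t(x, y, pooled_var: bool = False) -> TestResult:
    """Two-sided unpaired t-test; Welch (unequal variances) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("need at least 2 observations per group")
    if x.std() == 0 and y.std() == 0:
        p = 1.0 if x.mean() == y.mean() else 0.0
        return TestResult("x vs y", 0.0 if p == 1.0 else float("inf"), p,
                          "t (degenerate)", (x.size, y.size), flags=("zero_variance",))
    res = sps.ttest_ind(x, y, equal_var=pooled_var)
    return TestResult("x vs y", float(res.statistic), float(res.pvalue),
                      "t (pooled)" if pooled_var else "t (welch)", (x.size, y.size))


def signed_rank_vs_zero(x) -> TestResult:
    """One-sample Wilcoxon signed-rank test of median(x) = 0 (two-sided)."""
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    if x.size < 3:
        return TestResult("median vs 0", float("nan"), 1.0, "signed-rank (too few nonzero)",
                          (x.size,), flags=("low_n",))
    res = sps.wilcoxon(x, alternative="two-sided")
    return TestResult("median vs 0", float(res.statistic), float(res.pvalue),
                      "signed-rank", (x.size,))
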