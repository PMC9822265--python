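"""Nonparametric statistical battery with effect sizes.

From-scratch implementations of the rank tests used for small-sample,
non-normal electrophysiology and anatomy data: Friedman (with Kendall's W),
exact/asymptotic Wilcoxon signed-rank, exact/asymptotic Mann-Whitney U,
Kruskal-Wallis (with eta squared) plus Dunn post-hoc comparisons,
two-sample Kolmogorov-Smirnov, simple linear regression with an F-test, and
Bonferroni adjustment.

Midranks are used for ties throughout.  Exact null distributions are
computed by dynamic programming (signed-rank, U) or enumeration of group
labelings (U with ties, KS) within the documented size cutoffs; beyond
them, normal/chi-square approximations with tie and continuity corrections
are used.  Two-sided exact p-values are 2 x min(lower tail, upper tail),
capped at 1.  Distribution functions (normal, chi-square, F) come from
scipy.stats; everything else is computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "RegressionResult",
    "midrank",
    "friedman",
    "kendall_w_from_chi2",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "ks_two_sample",
    "linear_regression_f",
    "bonferroni",
    "DegenerateDataError",
    "WILCOXON_EXACT_MAX_N",
    "MWU_EXACT_MAX_PRODUCT",
]

#: Exact signed-rank null distribution is used up to this many non-zero pairs.
WILCOXON_EXACT_MAX_N = 25
#: Exact U distribution is used while n1 * n2 <= this.
MWU_EXACT_MAX_PRODUCT = 400
#: Enumeration over group labelings (ties, KS) while C(n, n1) <= this.
ENUMERATION_MAX_ARRANGEMENTS = 50_000


class DegenerateDataError(ValueError):
    """The test statistic is undefined for this input (e.g. all-zero
    differences)."""


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    n: Optional[Tuple[int, ...]] = None
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    method: str = "asymptotic"  # 'exact' or 'asymptotic'
    posthoc: Optional[pd.DataFrame] = None


@dataclass
class RegressionResult:
    beta0: float
    beta1: float
    f_statistic: float
    df: Tuple[int, int]
    p_value: float
    r_squared: float


def midrank(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the average (mid) rank."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_sum(values: np.ndarray) -> float:
    """Sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Friedman / Kendall's W
# ---------------------------------------------------------------------------


def kendall_w_from_chi2(chi2: float, n_subjects: int, k: int) -> float:
    """Kendall's coefficient of concordance W = chi2 / (N (k - 1))."""
    if n_subjects < 2 or k < 2:
        raise ValueError("need N >= 2 subjects and k >= 2 conditions")
    return chi2 / (n_subjects * (k - 1))


def friedman(data) -> TestResult:
    """Friedman test for k >= 3 repeated measures on N subjects.

    ``data`` is an (N, k) array (rows = subjects).  Within-subject midranks
    with tie correction; the statistic is chi-square distributed with k - 1
    df; the effect size is Kendall's W = chi2 / (N (k - 1)).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions array")
    n, k = x.shape
    if n < 2 or k < 3:
        raise ValueError("need N >= 2 subjects and k >= 3 conditions")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not allowed")
    ranks = np.vstack([midrank(row) for row in x])
    col_sums = ranks.sum(axis=0)
    chi2_raw = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    tie = sum(_tie_sum(row) for row in x)
    correction = 1.0 - tie / (n * k * (k**2 - 1))
    if correction <= 0:
        # every subject fully tied: no discrimination between conditions
        chi2 = 0.0
    else:
        chi2 = chi2_raw / correction
    p = float(_sps.chi2.sf(chi2, k - 1))
    w = kendall_w_from_chi2(chi2, n, k)
    return TestResult(
        test="friedman",
        statistic=chi2,
        p_value=p,
        df=k - 1,
        n=(n, k),
        effect_size=w,
        effect_size_name="kendall_w",
        method="asymptotic",
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_counts(double_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ over the 2^n sign assignments, by DP."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        new = counts.copy()
        new[r:] += counts[: len(counts) - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    The statistic is W+ = sum of the midranks of the positive differences
    (zeros dropped).  Exact p by the full sign-assignment null distribution
    for n <= 25; otherwise a normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = midrank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        dr = np.round(2.0 * ranks).astype(int)
        counts = _signed_rank_counts(dr)
        total = counts.sum()
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie = _tie_sum(np.abs(d))
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0)
        z = (abs(w_plus - mu) - 0.5) / sd  # continuity correction
        p = float(2.0 * _sps.norm.sf(z))
        method = "asymptotic"
    return TestResult(
        test="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p,
        n=(n,),
        method=method,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U over the C(n1+n2, n1) rank arrangements
    (no ties), by the insertion DP."""
    umax = n1 * n2
    dp = np.zeros((n1 + 1, umax + 1))
    dp[0, 0] = 1.0
    for m in range(1, n1 + n2 + 1):
        new = dp.copy()
        for i in range(min(m, n1), 0, -1):
            inc = m - i  # group-2 elements preceding the new group-1 element
            if inc > umax:
                continue
            new[i, inc:] += dp[i - 1, : umax + 1 - inc]
        dp = new
    return dp[n1]


def _two_sided_from_counts(counts: np.ndarray, obs: int) -> float:
    total = counts.sum()
    p_le = counts[: obs + 1].sum() / total
    p_ge = counts[obs:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The statistic is U for the first sample (rank-sum form, midranks).
    Exact p while n1*n2 <= 400 (dynamic programming without ties,
    labeling enumeration with ties); otherwise a normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = midrank(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2
    exact_ok = n1 * n2 <= MWU_EXACT_MAX_PRODUCT
    if exact_ok and not has_ties:
        counts = _u_counts(n1, n2)
        p = _two_sided_from_counts(counts, int(round(u1)))
        method = "exact"
    elif exact_ok and math.comb(n1 + n2, n1) <= ENUMERATION_MAX_ARRANGEMENTS:
        p = _enumerate_u_p(ranks, n1, u1)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie = _tie_sum(combined)
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
        p = float(2.0 * _sps.norm.sf(z))
        method = "asymptotic"
    return TestResult(
        test="mann_whitney_u",
        statistic=u1,
        p_value=p,
        n=(n1, n2),
        method=method,
    )


def _all_labelings(n: int, n1: int) -> np.ndarray:
    """Boolean matrix (C(n, n1), n): every way to mark n1 of n positions."""
    combs = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    mask = np.zeros((len(combs), n), dtype=bool)
    np.put_along_axis(mask, combs, True, axis=1)
    return mask


def _enumerate_u_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p with ties: enumerate every assignment of n1 of the
    observed ranks to group 1."""
    mask = _all_labelings(len(ranks), n1)
    us = mask @ ranks - n1 * (n1 + 1) / 2.0
    n_le = np.count_nonzero(us <= u_obs + 1e-9)
    n_ge = np.count_nonzero(us >= u_obs - 1e-9)
    total = len(us)
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn post-hoc
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across k independent groups, with tie
    correction; effect size eta^2 = (H - k + 1) / (n - k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n < 3:
        raise ValueError("need total n >= 3")
    combined = np.concatenate(groups)
    ranks = midrank(combined)
    h = 0.0
    start = 0
    for size in sizes:
        r = ranks[start : start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_sum(combined) / (n**3 - n)
    if correction <= 0:
        raise DegenerateDataError("all observations identical")
    h /= correction
    p = float(_sps.chi2.sf(h, k - 1))
    eta2 = (h - k + 1) / (n - k) if n > k else float("nan")
    return TestResult(
        test="kruskal_wallis",
        statistic=h,
        p_value=p,
        df=k - 1,
        n=tuple(sizes),
        effect_size=eta2,
        effect_size_name="eta_squared",
        method="asymptotic",
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise z tests on the pooled ranking after Kruskal-Wallis.

    z = (mean rank difference) / SE with tie-corrected SE; two-sided p,
    Bonferroni-adjusted over the m = k(k-1)/2 comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Dunn post-hoc needs at least 3 groups")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    combined = np.concatenate(groups)
    ranks = midrank(combined)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    tie_term = _tie_sum(combined) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * _sps.norm.sf(abs(z)))
        rows.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    f1 = np.searchsorted(xs, grid, side="right") / len(xs)
    f2 = np.searchsorted(ys, grid, side="right") / len(ys)
    return float(np.max(np.abs(f1 - f2)))


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    if lam <= 0:
        return 1.0
    terms = [
        2.0 * (-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        for k in range(1, 101)
    ]
    return float(min(1.0, max(0.0, sum(terms))))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |F1 - F2|.

    Exact p by enumeration of group labelings for small samples, otherwise
    the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    if math.comb(n1 + n2, n1) <= ENUMERATION_MAX_ARRANGEMENTS:
        combined = np.sort(np.concatenate([x, y]))
        n = n1 + n2
        mask = _all_labelings(n, n1)  # each row: which sorted points are 'x'
        f1 = np.cumsum(mask, axis=1) / n1
        f2 = np.cumsum(~mask, axis=1) / n2
        diffs = np.abs(f1 - f2)
        # with ties, the empirical CDFs may only be compared after the last
        # of each run of equal values
        valid = np.empty(n, dtype=bool)
        valid[:-1] = combined[:-1] != combined[1:]
        valid[-1] = True
        d_perm = diffs[:, valid].max(axis=1)
        p = float(np.count_nonzero(d_perm >= d - 1e-12)) / len(d_perm)
        method = "exact"
    else:
        p = _ks_asymptotic_p(d, n1, n2)
        method = "asymptotic"
    return TestResult(
        test="ks_two_sample",
        statistic=d,
        p_value=p,
        n=(n1, n2),
        method=method,
    )


# ---------------------------------------------------------------------------
# Regression and multiple-comparison adjustment
# ---------------------------------------------------------------------------


def linear_regression_f(x, y) -> RegressionResult:
    """Ordinary least squares y = b0 + b1 x with the overall F-test.

    F = MSR / MSE on (1, n - 2) df; an exact fit reports F = inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need n >= 3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("singular design: x is constant")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    beta0 = float(y.mean() - beta1 * x.mean())
    fitted = beta0 + beta1 * x
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse
    df = (1, n - 2)
    if sst == 0:
        r2 = 1.0 if sse == 0 else 0.0
    else:
        r2 = max(0.0, min(1.0, ssr / sst))
    if sse <= 1e-12 * max(sst, 1.0):
        return RegressionResult(beta0, beta1, float("inf"), df, 0.0, r2)
    f_stat = ssr / (sse / (n - 2))
    p = float(_sps.f.sf(f_stat, *df))
    return RegressionResult(beta0, beta1, f_stat, df, p, r2)


def bonferroni(p_values, m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)
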