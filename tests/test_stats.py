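"""Nonparametric test battery: enumeration oracles, reference agreement,
effect sizes and algebraic identities."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ecphys.stats import (
    DegenerateDataError,
    bonferroni,
    dunn_posthoc,
    friedman,
    kendall_w_from_chi2,
    kruskal_wallis,
    ks_two_sample,
    linear_regression_f,
    mann_whitney_u,
    midrank,
    wilcoxon_signed_rank,
)


# -- independent brute-force oracles (pure enumeration, no shared code) -----


def brute_wilcoxon_p(d):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = midrank(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((1, -1), repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s > 0))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_mwu_p(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    ranks = midrank(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for subset in itertools.combinations(range(len(ranks)), n1):
        us.append(ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    return min(1.0, 2.0 * min((us <= u_obs + 1e-9).mean(),
                              (us >= u_obs - 1e-9).mean()))


def brute_ks_p(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    combined = np.concatenate([x, y])

    def ks_d(a, b):
        grid = np.concatenate([a, b])
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    d_obs = ks_d(x, y)
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        mask = np.zeros(len(combined), dtype=bool)
        mask[list(subset)] = True
        count += ks_d(combined[mask], combined[~mask]) >= d_obs - 1e-12
        total += 1
    return count / total


class TestFriedman:
    def test_perfect_concordance(self):
        data = np.array([[1.0, 2.0, 3.0]] * 3) + np.arange(3)[:, None] * 10
        res = friedman(data)
        assert res.statistic == pytest.approx(6.0)  # N (k-1)
        assert res.effect_size == pytest.approx(1.0)

    def test_identical_conditions_give_zero(self):
        data = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = friedman(data)
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_w_from_printed_chi2(self):
        assert kendall_w_from_chi2(32.8, 11, 5) == pytest.approx(0.745, abs=5e-4)

    def test_matches_reference_on_continuous_data(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            data = rng.normal(0, 1, (rng.integers(5, 12), rng.integers(3, 6)))
            res = friedman(data)
            ref = sps.friedmanchisquare(*(data[:, j] for j in range(data.shape[1])))
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman(data)

    def test_rank_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (8, 4))
        a = friedman(data)
        b = friedman(np.exp(data))  # strictly increasing transform
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)


class TestWilcoxon:
    def test_all_positive_n11_statistic_is_66(self):
        res = wilcoxon_signed_rank(np.arange(1, 12, dtype=float))
        assert res.statistic == 66.0
        assert res.method == "exact"

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_exact_p_equals_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            d = rng.normal(0.3, 1.0, n)
            if rng.random() < 0.3:
                d = np.round(d, 1)  # induce tied magnitudes
            d = d[d != 0]
            if len(d) == 0:
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_matches_reference_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = rng.normal(0.5, 1.0, int(rng.integers(5, 15)))
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_reference_asymptotic(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            d = rng.normal(0.2, 1.0, 40)
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="approx", correction=True)
            assert res.method == "asymptotic"
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestMannWhitney:
    def test_identical_multisets_give_central_u(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney_u(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2.0)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic in (0.0, 9.0)

    def test_exact_p_equals_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            if rng.random() < 0.3:
                x, y = np.round(x, 0), np.round(y, 0)  # ties across groups
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(brute_mwu_p(x, y), abs=1e-12)

    def test_matches_reference(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.normal(0, 1, int(rng.integers(4, 12)))
            y = rng.normal(0.4, 1, int(rng.integers(4, 12)))
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_reference_asymptotic(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.3, 1, 28)
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert res.method == "asymptotic"
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestKruskalWallis:
    def test_all_equal_gives_zero(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([np.ones(5), np.ones(4)])

    def test_two_groups_equal_squared_standardized_u(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 10)
        h = kruskal_wallis([x, y]).statistic
        u = mann_whitney_u(x, y).statistic
        n1, n2 = len(x), len(y)
        z = (u - n1 * n2 / 2.0) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_matches_reference(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            gs = [rng.normal(0, 1, int(rng.integers(4, 10))) for _ in range(3)]
            res = kruskal_wallis(gs)
            ref = sps.kruskal(*gs)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_eta_squared_formula(self):
        gs = [np.array([1.0, 2.0]), np.array([5.0, 6.0]), np.array([9.0, 10.0])]
        res = kruskal_wallis(gs)
        n, k = 6, 3
        assert res.effect_size == pytest.approx((res.statistic - k + 1) / (n - k))


class TestDunn:
    def test_identical_groups_have_zero_z(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        table = dunn_posthoc([g, g, g + 100.0])
        row = table[table["pair"] == "g1 vs g2"].iloc[0]
        assert row["z"] == pytest.approx(0.0)
        assert row["p_adjusted"] == pytest.approx(1.0)

    def test_number_of_comparisons(self):
        rng = np.random.default_rng(10)
        table = dunn_posthoc([rng.normal(0, 1, 5) for _ in range(5)])
        assert len(table) == 10  # k(k-1)/2 with k=5

    def test_pairwise_z_matches_mean_rank_formula(self):
        # hand-checkable: no ties, equal sizes
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([4.0, 5.0, 6.0])
        g3 = np.array([7.0, 8.0, 9.0])
        table = dunn_posthoc([g1, g2, g3])
        n = 9
        se = math.sqrt(n * (n + 1) / 12.0 * (2.0 / 3.0))
        z12 = (2.0 - 5.0) / se
        row = table[table["pair"] == "g1 vs g2"].iloc[0]
        assert row["z"] == pytest.approx(z12, abs=1e-9)


class TestKolmogorovSmirnov:
    def test_identical_multisets_have_zero_d(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        res = ks_two_sample(x, x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_have_d_one(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
        assert res.statistic == 1.0

    def test_exact_p_equals_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            res = ks_two_sample(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_ks_p(x, y), abs=1e-12)

    def test_matches_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(4, 8)))
            y = rng.normal(0.5, 1, int(rng.integers(4, 8)))
            res = ks_two_sample(x, y)
            ref = sps.ks_2samp(x, y, method="exact")
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestRegression:
    def test_exact_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linear_regression_f(x, 2.0 * x + 1.0)
        assert res.beta0 == pytest.approx(1.0)
        assert res.beta1 == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert math.isinf(res.f_statistic) and res.p_value == 0.0

    def test_four_point_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.5, 4.0, 5.0])
        res = linear_regression_f(x, y)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.beta0 == pytest.approx(beta[0], abs=1e-12)
        assert res.beta1 == pytest.approx(beta[1], abs=1e-12)

    def test_matches_reference_f_and_p(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            x = rng.normal(0, 1, 20)
            y = 0.5 * x + rng.normal(0, 1, 20)
            res = linear_regression_f(x, y)
            ref = sps.linregress(x, y)
            assert res.beta1 == pytest.approx(ref.slope, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
            assert res.r_squared == pytest.approx(ref.rvalue**2, abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            linear_regression_f(np.ones(5), np.arange(5.0))


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [(0.004, 10, 0.04), (0.2, 10, 1.0)])
    def test_examples(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)

    def test_order_preserved(self):
        rng = np.random.default_rng(14)
        p = np.sort(rng.uniform(0, 0.2, 20))
        adj = bonferroni(p, 30)
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 5)


class TestRankInvariance:
    def test_tests_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 10)
        f = lambda v: np.exp(3.0 * v)  # strictly increasing
        assert mann_whitney_u(x, y).statistic == pytest.approx(
            mann_whitney_u(f(x), f(y)).statistic
        )
        gs = [rng.normal(0, 1, 8) for _ in range(3)]
        assert kruskal_wallis(gs).statistic == pytest.approx(
            kruskal_wallis([f(g) for g in gs]).statistic, abs=1e-9
        )
        dz = dunn_posthoc(gs)["z"].to_numpy()
        dz_t = dunn_posthoc([f(g) for g in gs])["z"].to_numpy()
        np.testing.assert_allclose(dz, dz_t, atol=1e-9)
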