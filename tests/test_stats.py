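"""Outlier fences, normality screen, KW+Dunn, Mann-Whitney, two-way ANOVA."""

import numpy as np
import pytest

from microca.stats import (
    GroupedValues,
    kruskal_dunn,
    ks_normality,
    mann_whitney,
    median_iqr,
    tukey_outliers,
    twoway_bonferroni,
)


def grouped(*arrays, labels=None, **kw):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    vals = np.concatenate([np.asarray(a, float) for a in arrays])
    labs = np.concatenate(
        [np.full(len(a), lab) for a, lab in zip(arrays, labels)]
    )
    return GroupedValues(vals, labs, **kw)


class TestDescriptives:
    def test_median_iqr_basic(self):
        out = median_iqr([1, 2, 3, 4, 5])
        assert out["median"] == 3.0
        assert out["iqr"] == 2.0

    def test_single_value_iqr_zero(self):
        out = median_iqr([7.0])
        assert out["median"] == 7.0 and out["iqr"] == 0.0

    def test_unordered_values(self):
        assert median_iqr([50, 37.5, 62.5, 45, 55])["median"] == 50.0

    def test_whisker_percentiles_present(self):
        out = median_iqr(np.arange(101))
        assert out["p10"] == 10.0 and out["p90"] == 90.0


class TestTukeyOutliers:
    def test_single_extreme_value_flagged(self):
        vals = np.array(list(range(1, 10)) + [100], dtype=float)
        mask = tukey_outliers(vals)
        # fences: Q1=3.25, Q3=7.75 -> [-3.5, 14.5]; only 100 outside
        assert mask.sum() == 9
        assert not mask[-1]

    def test_identical_values_never_flagged(self):
        assert tukey_outliers(np.full(10, 4.2)).all()

    def test_symmetric_data_within_fences(self):
        assert tukey_outliers(np.array([-2.0, -1, 0, 1, 2])).all()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tukey_outliers([1.0, 2.0, 3.0])


class TestKsNormality:
    def test_normal_draws_rarely_rejected(self):
        passes = sum(
            ks_normality(np.random.default_rng(s).normal(0, 1, 1000)) > 0.05
            for s in range(100)
        )
        assert passes >= 90

    def test_exponential_draws_rejected(self):
        rejects = sum(
            ks_normality(np.random.default_rng(s).exponential(1.0, 1000)) < 0.05
            for s in range(100)
        )
        assert rejects >= 95

    def test_small_sample_and_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="variance"):
            ks_normality(np.full(10, 1.0))


class TestKruskalDunn:
    def test_identical_groups_null_identity(self):
        g = grouped([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4])
        res = kruskal_dunn(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9
        assert res.pairwise == []

    def test_exact_p_matches_permutation_oracle(self, rng):
        # fully separated groups at N = 9: exact enumeration vs Monte Carlo
        g = grouped([1, 2, 3], [4, 5, 6], [7, 8, 9])
        res = kruskal_dunn(g)
        assert res.details["p_method"] == "exact"
        assert res.p_value == pytest.approx(6 / 1680, abs=1e-12)
        # independent Monte-Carlo permutation of the pooled values
        from microca.stats import _kw_statistic

        pooled = np.arange(1.0, 10.0)
        h_obs = _kw_statistic(pooled, [3, 3, 3])
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            h = _kw_statistic(rng.permutation(pooled), [3, 3, 3])
            hits += h >= h_obs - 1e-12
        mc_p = hits / n_mc
        assert res.p_value == pytest.approx(mc_p, abs=3 * np.sqrt(mc_p / n_mc) + 1e-3)

    def test_dunn_pairwise_hand_computed(self):
        # mean ranks 2/5/8, SE = sqrt(5); z13 = 2.683 -> p_adj = 3 x 0.00729
        res = kruskal_dunn(grouped([1, 2, 3], [4, 5, 6], [7, 8, 9]))
        adj = {frozenset((a, b)): p for a, b, p in res.pairwise}
        assert adj[frozenset(("g0", "g2"))] == pytest.approx(3 * 0.0072923, rel=1e-3)
        assert adj[frozenset(("g0", "g1"))] == pytest.approx(3 * 0.179712, rel=1e-3)

    def test_large_samples_use_chi2(self):
        rng = np.random.default_rng(0)
        g = grouped(rng.normal(size=10), rng.normal(size=10), rng.normal(size=10))
        res = kruskal_dunn(g)
        assert res.details["p_method"] == "chi2"
        from scipy.stats import kruskal

        vals = g.groups()
        ref = kruskal(*vals.values())
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_label_permutation_invariance(self, rng):
        vals = rng.normal(size=24)
        labs = np.repeat(["a", "b", "c"], 8)
        g1 = GroupedValues(vals, labs)
        perm = rng.permutation(24)
        g2 = GroupedValues(vals[perm], labs[perm])
        assert kruskal_dunn(g1).p_value == pytest.approx(kruskal_dunn(g2).p_value)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=30)
        labs = np.repeat(["a", "b", "c"], 10)
        p1 = kruskal_dunn(GroupedValues(vals, labs)).p_value
        p2 = kruskal_dunn(GroupedValues(np.exp(vals), labs)).p_value
        assert p1 == pytest.approx(p2)

    def test_small_group_named_in_error(self):
        with pytest.raises(ValueError, match="g1"):
            kruskal_dunn(grouped([1, 2, 3], [1, 2], [1, 2, 3]))

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            kruskal_dunn(grouped([1, 2, 3], [4, 5, 6]))


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        res = mann_whitney([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.p_value > 0.9

    def test_exact_minimum_two_sided_p_for_full_separation(self):
        # smallest attainable two-sided exact p at n = 3 vs 3 is 2/C(6,3)
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_enumeration(self):
        from itertools import combinations
        from scipy.stats import mannwhitneyu

        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        res = mann_whitney(a, b)
        pooled = np.array(a + b)
        u_obs = mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
        n = 3
        us = []
        for idx in combinations(range(6), n):
            aa = pooled[list(idx)]
            bb = np.delete(pooled, list(idx))
            ranks = np.argsort(np.argsort(np.concatenate([aa, bb]))) + 1
            us.append(ranks[:n].sum() - n * (n + 1) / 2)
        us = np.array(us)
        mirror = n * n - u_obs
        lo, hi = min(u_obs, mirror), max(u_obs, mirror)
        p_enum = np.mean((us <= lo) | (us >= hi))
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0, 2.0], [3.0, 4.0, 5.0])

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(np.exp(a), np.exp(b)).p_value
        )


class TestTwoWayBonferroni:
    def make(self, effect_a=0.0, effect_int=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows_v, rows_a, rows_b = [], [], []
        for i, a in enumerate(["young", "middle", "old"]):
            for j, b in enumerate(["male", "female"]):
                v = rng.normal(0, 1, n) + effect_a * i + effect_int * i * j
                rows_v.append(v)
                rows_a += [a] * n
                rows_b += [b] * n
        return GroupedValues(
            np.concatenate(rows_v), np.array(rows_a), labels2=np.array(rows_b)
        )

    def test_identical_values_degenerate_null(self):
        g = GroupedValues(
            np.full(24, 3.0),
            np.repeat(["a", "b"], 12),
            labels2=np.tile(np.repeat(["x", "y"], 6), 2),
        )
        res = twoway_bonferroni(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_additive_main_effect_detected_without_interaction(self):
        detected = interaction_fp = 0
        for seed in range(30):
            res = twoway_bonferroni(self.make(effect_a=1.5, seed=seed))
            detected += res.details["p_A"] < 0.05
            interaction_fp += res.p_value < 0.05
        assert detected >= 28
        assert interaction_fp <= 4

    def test_balanced_design_type2_equals_type1(self):
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        g = self.make(effect_a=0.8, seed=3)
        res = twoway_bonferroni(g)
        df = pd.DataFrame({"y": g.values, "A": g.labels, "B": g.labels2})
        model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        assert res.details["F_A"] == pytest.approx(t1.loc["C(A)", "F"])
        assert res.details["F_B"] == pytest.approx(t1.loc["C(B)", "F"])

    def test_bonferroni_adjustment_is_m_times_raw(self):
        from scipy import stats as sstats
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        g = self.make(effect_a=1.0, seed=7)
        res = twoway_bonferroni(g)
        m = res.details["n_comparisons"]
        assert m == len(res.pairwise) == 6  # 3 age pairs x 2 sexes
        # recompute one raw p and check the multiplied adjustment
        df = pd.DataFrame({"y": g.values, "A": g.labels, "B": g.labels2})
        model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        mse = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
        a_lab, b_lab, p_adj = res.pairwise[0]
        la, lev = a_lab.split("|")
        lb, _ = b_lab.split("|")
        ya = df[(df.A == la) & (df.B == lev)]["y"]
        yb = df[(df.A == lb) & (df.B == lev)]["y"]
        t = (ya.mean() - yb.mean()) / np.sqrt(mse * (1 / len(ya) + 1 / len(yb)))
        p_raw = 2 * sstats.t.sf(abs(t), table.loc["Residual", "df"])
        assert p_adj == pytest.approx(min(1.0, m * p_raw))

    def test_empty_cell_named_in_error(self):
        g = GroupedValues(
            np.arange(12.0),
            np.array(["a"] * 6 + ["b"] * 6),
            labels2=np.array(["x"] * 6 + ["x"] * 3 + ["y"] * 3),
        )
        with pytest.raises(ValueError, match="'a' × 'y'"):
            twoway_bonferroni(g)

    def test_missing_second_factor_rejected(self):
        with pytest.raises(ValueError, match="second factor"):
            twoway_bonferroni(grouped([1, 2, 3], [4, 5, 6]))


class TestGroupedValues:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GroupedValues(np.arange(3.0), np.array(["a", "b"]))
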