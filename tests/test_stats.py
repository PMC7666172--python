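"""The statistics layer against independent oracles: hypergeometric
enumeration for Fisher, permutation enumeration for KS, closed-form sums
of squares for the ANOVAs, and statsmodels for the ANCOVA F tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as spstats

from stresssleep.stats import (
    ContingencyTable2x2,
    ancova_compare,
    fisher_exact_two_sided,
    ks_two_sample,
    oneway_anova_tukey,
    pearson_test,
    sidak_adjust,
    twoway_rm_anova_sidak,
    unpaired_t,
)


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # P(table with top-left cell x)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_test([0, 1, 2], [0, 1, 2])
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = pearson_test([0, 1, 2, 3], [0, -1, -2, -3])
        assert res.statistic == pytest.approx(-1.0)

    def test_t_transform_consistency(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_test(x, y)
        r = res.statistic
        t = r * np.sqrt((20 - 2) / (1 - r * r))
        p = 2 * spstats.t.sf(abs(t), 18)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 1, 2, 7), 0.04056),
            ((5, 1, 7, 6), 0.3331),
        ],
    )
    def test_reconstructed_proportion_tables(self, table, expected):
        res = fisher_exact_two_sided(ContingencyTable2x2(*table))
        assert res.p == pytest.approx(expected, rel=5e-3)
        assert res.p == pytest.approx(fisher_oracle(*table), rel=1e-9)

    def test_degenerate_column(self):
        res = fisher_exact_two_sided(ContingencyTable2x2(0, 4, 0, 6))
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            res = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            assert res.p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_invariant_to_row_and_column_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 10, size=4))
            if a + b + c + d == 0:
                continue
            p1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p
            p2 = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a)).p
            assert p1 == pytest.approx(p2, abs=1e-12)
            assert 0 < p1 <= 1

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestKS:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ks_two_sample(x, list(x)).statistic == pytest.approx(0.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == pytest.approx(1.0)

    def test_exact_p_matches_permutation_oracle(self, rng):
        # enumerate all C(m+n, m) orderings for tiny samples (no ties)
        m, n = 4, 4
        for _ in range(5):
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            res = ks_two_sample(x, y)
            pooled = np.concatenate([x, y])
            count = 0
            total = 0
            for idx in itertools.combinations(range(m + n), m):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                d = spstats.ks_2samp(xs, ys, method="asymp").statistic
                total += 1
                if d >= res.statistic - 1e-12:
                    count += 1
            assert res.p == pytest.approx(count / total, abs=1e-9)

    def test_large_samples_use_asymptotic(self, rng):
        x = rng.normal(size=150)
        y = rng.normal(size=150)
        res = ks_two_sample(x, y)
        assert res.extra["p_method"] == "asymp"


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=11)
        omni, _ = oneway_anova_tukey([x, y])
        t = unpaired_t(x, y)
        assert omni.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert omni.p == pytest.approx(t.p, rel=1e-9)

    def test_textbook_three_groups_hand_computed(self):
        # sums of squares computed by hand from the cell totals
        g1 = np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0])
        g2 = np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0])
        g3 = np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])
        grand = np.concatenate([g1, g2, g3]).mean()
        ss_between = 6 * sum((g.mean() - grand) ** 2 for g in (g1, g2, g3))
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in (g1, g2, g3))
        f_hand = (ss_between / 2) / (ss_within / 15)
        omni, pairs = oneway_anova_tukey([g1, g2, g3])
        assert omni.statistic == pytest.approx(f_hand, rel=1e-12)
        assert omni.df == (2, 15)
        # Tukey q from the studentized-range distribution, pair (g1, g3)
        se = np.sqrt(ss_within / 15 / 6)
        q = abs(g1.mean() - g3.mean()) / se
        p_q = spstats.studentized_range.sf(q, 3, 15)
        pair = [p for p in pairs if p.comparison == "g0 vs g2"][0]
        assert pair.adjusted_p == pytest.approx(p_q, rel=1e-4)

    def test_tukey_adjusted_at_least_unadjusted(self, rng):
        groups = [rng.normal(size=7) for _ in range(4)]
        _, pairs = oneway_anova_tukey(groups)
        for p in pairs:
            assert p.adjusted_p >= p.p - 1e-12

    def test_identical_constant_groups_degenerate(self):
        omni, pairs = oneway_anova_tukey([np.ones(4), np.ones(5)])
        assert omni.degenerate
        assert pairs == []


class TestMixedAnova:
    def _balanced(self, rng):
        groups = ["a"] * 6 + ["b"] * 6
        values = rng.normal(size=(12, 2))
        return values, groups

    def test_identical_levels_give_zero_within_f(self, rng):
        base = rng.normal(size=12)
        values = np.column_stack([base, base])
        groups = ["a"] * 6 + ["b"] * 6
        omnibus, _ = twoway_rm_anova_sidak(values, groups)
        by = {o.comparison: o for o in omnibus}
        assert by["level"].statistic == pytest.approx(0.0, abs=1e-9)
        assert by["Interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_sidak_single_comparison_is_identity(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(1.0, 3) == 1.0
        assert sidak_adjust(0.2, 3) > 0.2

    def test_balanced_design_matches_sums_of_squares_oracle(self, rng):
        values, groups = self._balanced(rng)
        omnibus, _ = twoway_rm_anova_sidak(values, groups)
        by = {o.comparison: o for o in omnibus}
        # independent cell-means decomposition for the balanced mixed design
        k, n_per, N = 2, 6, 12
        grand = values.mean()
        subj_means = values.mean(axis=1)
        garr = np.array(groups)
        group_means = {g: values[garr == g].mean() for g in "ab"}
        level_means = values.mean(axis=0)
        ss_group = sum(
            2 * n_per * (group_means[g] - grand) ** 2 for g in "ab"
        )
        ss_subj = 2 * ((subj_means - grand) ** 2).sum()
        ss_err_between = ss_subj - ss_group
        ss_level = N * ((level_means - grand) ** 2).sum()
        cell = {
            (g, l): values[garr == g, l].mean() for g in "ab" for l in (0, 1)
        }
        ss_cells = sum(
            n_per * (cell[(g, l)] - grand) ** 2 for g in "ab" for l in (0, 1)
        )
        ss_inter = ss_cells - ss_group - ss_level
        ss_total = ((values - grand) ** 2).sum()
        ss_err_within = ss_total - ss_subj - ss_level - ss_inter
        f_group = (ss_group / 1) / (ss_err_between / 10)
        f_level = (ss_level / 1) / (ss_err_within / 10)
        f_inter = (ss_inter / 1) / (ss_err_within / 10)
        assert by["group"].statistic == pytest.approx(f_group, rel=1e-6)
        assert by["level"].statistic == pytest.approx(f_level, rel=1e-6)
        assert by["Interaction"].statistic == pytest.approx(f_inter, rel=1e-6)

    def test_within_followups_are_paired_t(self, rng):
        values, groups = self._balanced(rng)
        _, follow = twoway_rm_anova_sidak(values, groups, comparisons="within")
        res = spstats.ttest_rel(values[:6, 0], values[:6, 1])
        assert follow[0].p == pytest.approx(float(res.pvalue), rel=1e-9)
        assert follow[0].adjusted_p == pytest.approx(
            sidak_adjust(float(res.pvalue), 2), rel=1e-9
        )

    def test_missing_cells_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0], [1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            twoway_rm_anova_sidak(values, ["a", "a", "b", "b"])


class TestAncova:
    def test_noiseless_parallel_lines(self):
        x = np.arange(6.0)
        res = ancova_compare([(x, 2 * x), (x, 2 * x + 1)])
        assert res.degenerate
        assert res.p_slope_equal == pytest.approx(1.0)
        assert res.common_slope == pytest.approx(2.0)
        diff = res.group_intercepts[1] - res.group_intercepts[0]
        assert diff == pytest.approx(1.0, abs=1e-9)
        assert res.p_intercept_equal == pytest.approx(0.0)

    def test_single_group_degenerates_to_ols(self, rng):
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(size=10)
        res = ancova_compare([(x, y)])
        fit = res.group_fits[0]
        assert res.p_slope_equal == 1.0
        assert res.common_slope == pytest.approx(fit.slope, rel=1e-9)
        assert res.group_intercepts[0] == pytest.approx(fit.intercept, rel=1e-6)

    def test_matches_statsmodels_f_tests(self, rng):
        import pandas as pd
        import statsmodels.formula.api as smf

        for _ in range(10):
            xs = [rng.normal(size=12), rng.normal(size=15)]
            ys = [
                1.0 + 0.5 * xs[0] + rng.normal(size=12),
                0.5 + 0.8 * xs[1] + rng.normal(size=15),
            ]
            res = ancova_compare(list(zip(xs, ys)), alpha=0.0)  # always run both
            df = pd.DataFrame(
                {
                    "x": np.concatenate(xs),
                    "y": np.concatenate(ys),
                    "g": ["a"] * 12 + ["b"] * 15,
                }
            )
            full = smf.ols("y ~ x * g", data=df).fit()
            cs = smf.ols("y ~ x + g", data=df).fit()
            single = smf.ols("y ~ x", data=df).fit()
            from statsmodels.stats.anova import anova_lm

            p_slope = anova_lm(cs, full).iloc[1]["Pr(>F)"]
            p_int = anova_lm(single, cs).iloc[1]["Pr(>F)"]
            assert res.p_slope_equal == pytest.approx(p_slope, rel=1e-6)
            assert res.p_intercept_equal == pytest.approx(p_int, rel=1e-6)

    def test_planted_slope_difference_detected(self, rng):
        hits = 0
        for _ in range(50):
            x1, x2 = rng.normal(size=15), rng.normal(size=15)
            y1 = 1.0 * x1 + rng.normal(0, 0.3, 15)
            y2 = 2.5 * x2 + rng.normal(0, 0.3, 15)
            if ancova_compare([(x1, y1), (x2, y2)]).p_slope_equal < 0.01:
                hits += 1
        assert hits >= 48

    def test_intercept_test_suppressed_when_slopes_differ(self, rng):
        x = np.linspace(0, 1, 20)
        res = ancova_compare(
            [(x, 5 * x + rng.normal(0, 0.05, 20)), (x, -5 * x + rng.normal(0, 0.05, 20))]
        )
        assert res.p_slope_equal < 0.05
        assert res.p_intercept_equal is None


class TestUnpairedT:
    def test_identical_samples(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_variant(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 5, 12)
        pooled = unpaired_t(x, y)
        welch = unpaired_t(x, y, welch=True)
        assert welch.method == "welch_t"
        assert welch.df != pooled.df

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])
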