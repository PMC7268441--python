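"""Standardized proliferation and group-comparison statistics."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from mitozones.datasets import groups_with_means
from mitozones.geometry import InvalidParameterError
from mitozones.groupstats import (
    StageSeries,
    anova_oneway,
    percent_change,
    shapiro_wilk,
    standardize,
    tukey_hsd,
    wilcoxon_pairwise,
)


class TestStandardize:
    @pytest.mark.parametrize("ph3,dapi,expected", [(0, 500, 0.0), (50, 1000, 5.0)])
    def test_simple_ratios(self, ph3, dapi, expected):
        assert standardize(ph3, dapi) == expected

    def test_matches_exact_arithmetic(self):
        assert standardize(24, 991) == pytest.approx(float(Fraction(2400, 991)), abs=1e-12)

    def test_zero_dapi_rejected(self):
        with pytest.raises(InvalidParameterError):
            standardize(10, 0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "values,expected",
        [((200, 100), (-50.0,)), ((100, 900), (800.0,)), ((100, 100), (0.0,))],
    )
    def test_transitions(self, values, expected):
        out = percent_change(StageSeries(("a", "b"), values))
        assert out.percent_change == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            percent_change(StageSeries(("a", "b"), (0, 10)))


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self):
        g = {"a": [1.0, 2, 3], "b": [2.0, 3, 4]}
        res = anova_oneway(g)
        t = sps.ttest_ind(g["a"], g["b"], equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-12)

    def test_degenerate_zero_variance_flagged_infinite(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            res = anova_oneway({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        assert np.isinf(res.f_statistic)
        assert res.degenerate

    def test_reference_contrasts_match_scipy_dunnett(self):
        # moderate effect sizes: scipy's Dunnett p-values come from
        # randomized quasi-Monte-Carlo integration, and their run-to-run
        # spread is small only away from the distribution tails
        g = {"MN": [1.0, 1.3, 1.4], "CP": [1.5, 1.8, 1.9], "GS": [1.2, 1.5, 1.3]}
        res = anova_oneway(g, reference="MN", adjust="dunnett")
        oracle = sps.dunnett(g["CP"], g["GS"], control=g["MN"])
        got = dict(zip(res.comparisons.group, res.comparisons.p_adj))
        assert got["CP"] == pytest.approx(oracle.pvalue[0], abs=5e-3)
        assert got["GS"] == pytest.approx(oracle.pvalue[1], abs=5e-3)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InvalidParameterError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestTukey:
    def test_identical_groups(self):
        table = tukey_hsd({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert table.difference.iloc[0] == 0.0
        assert table.p_adj.iloc[0] == pytest.approx(1.0)

    def test_difference_depends_only_on_means(self):
        # three-replicate groups with means matching the published
        # four-species proliferation summaries
        for spread in (0.05, 0.3):
            g = groups_with_means(
                {"MN": 1.208, "GS": 1.332, "CP": 2.423, "AJ": 2.055}, spread=spread
            )
            table = tukey_hsd(g).set_index("pair")
            assert table.loc["CP-AJ", "difference"] == pytest.approx(0.368, abs=1e-12)
            assert table.loc["MN-AJ", "difference"] == pytest.approx(-0.847, abs=1e-12)
            assert table.loc["MN-CP", "difference"] == pytest.approx(-1.215, abs=1e-12)

    def test_antisymmetry_and_mean_consistency(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(i, 1, 5) for i, k in enumerate("abc")}
        table = tukey_hsd(g).set_index("pair")
        for a, b in itertools.combinations(sorted(g), 2):
            assert table.loc[f"{b}-{a}", "difference"] == pytest.approx(
                g[b].mean() - g[a].mean(), abs=1e-12
            )

    def test_p_adj_against_numeric_studentized_range_oracle(self):
        g = {
            "a": [1.1, 2.0, 2.9, 1.8],
            "b": [2.4, 3.1, 2.2, 3.3],
            "c": [0.7, 1.9, 1.2, 1.5],
        }
        k = 3
        df = 9
        table = tukey_hsd(g).set_index("pair")
        ms_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in g.values()) / df

        def sr_sf(q):
            # survival function of the studentized range by direct
            # numerical integration (independent of scipy's implementation)
            def inner(s):
                def z_int(z):
                    return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (
                        k - 1
                    )

                zi = integrate.quad(z_int, -8, 8, limit=200)[0]
                import math

                chi_pdf = (
                    2 * (df / 2) ** (df / 2) / math.gamma(df / 2)
                    * s ** (df - 1) * np.exp(-df * s**2 / 2)
                )
                return k * zi * chi_pdf

            return 1 - integrate.quad(inner, 1e-6, 5, limit=200)[0]

        for pair in table.index:
            b, a = pair.split("-")
            se = np.sqrt(ms_within * (1 / 4 + 1 / 4))
            q_obs = abs(np.mean(g[b]) - np.mean(g[a])) / (se / np.sqrt(2))
            assert table.loc[pair, "p_adj"] == pytest.approx(sr_sf(q_obs), abs=1e-4)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        mat = wilcoxon_pairwise({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert mat.loc["a", "b"] == 1.0

    def test_exact_p_by_enumeration(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 rank splits,
        # two-sided p = 2/20 = 0.1
        mat = wilcoxon_pairwise({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        ranks = range(1, 7)
        u_obs = 0  # all b exceed all a
        count = 0
        for combo in itertools.combinations(ranks, 3):
            u = sum(combo) - 6  # rank-sum minus minimum
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        expected = count / 20
        assert expected == 0.1
        assert mat.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_holm_adjustment_structure(self):
        g = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [2.5, 3.5, 4.5]}
        raw = {}
        for x, y in itertools.combinations(sorted(g), 2):
            raw[(x, y)] = sps.mannwhitneyu(g[x], g[y], alternative="two-sided",
                                           method="exact").pvalue
        # manual Holm
        items = sorted(raw.items(), key=lambda kv: kv[1])
        m = len(items)
        adj, running = {}, 0.0
        for i, (pair, p) in enumerate(items):
            running = max(running, (m - i) * p)
            adj[pair] = min(running, 1.0)
        mat = wilcoxon_pairwise(g, adjustment="holm")
        for (x, y), p in adj.items():
            assert mat.loc[x, y] == pytest.approx(p, abs=1e-12)

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                  use_continuity=True).pvalue
        assert abs(exact - approx) <= 0.02


class TestShapiroWilk:
    def test_perfect_normal_spacing(self):
        q = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, _ = shapiro_wilk(q)
        assert w > 0.99

    def test_rejects_uniform_data(self):
        rng = np.random.default_rng(0)
        hits = sum(shapiro_wilk(rng.uniform(0, 1, 200))[1] < 0.05 for _ in range(50))
        assert hits >= 45

    @pytest.mark.parametrize("n", [2, 5001])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(InvalidParameterError):
            shapiro_wilk(np.zeros(n))
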