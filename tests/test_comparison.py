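import numpy as np
import pytest
from scipy import stats

from chronoveg import (
    compare_metric,
    games_howell,
    levene_test,
    one_way_anova,
    route_comparison,
    shapiro_wilk,
    tukey_hsd,
    welch_anova,
)
from chronoveg.errors import DomainError


class TestClassicAnova:
    def test_hand_computed_f(self):
        # SSB = 14, SSW = 6 -> F = (14/2)/(6/6) = 7
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [4, 5, 6]])
        assert res.statistic == pytest.approx(7.0)
        assert (res.df1, res.df2) == (2.0, 6.0)
        assert res.variant == "classic"

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_location_invariance(self):
        g = [[1.0, 2.5, 3.1], [2.2, 3.3, 4.0], [4.1, 5.0, 6.2]]
        shifted = [[v + 100 for v in grp] for grp in g]
        assert one_way_anova(g).statistic == pytest.approx(
            one_way_anova(shifted).statistic
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(DomainError):
            one_way_anova([[1, 2], [3]])


class TestWelchAnova:
    def test_two_groups_match_classic_under_equal_variance(self):
        # k = 2 with equal sample variances: Welch F equals classic F
        g = [[1.0, 2.0, 3.0], [5.0, 6.0, 7.0]]
        assert welch_anova(g).statistic == pytest.approx(
            one_way_anova(g).statistic
        )

    def test_close_to_classic_on_homoscedastic_balanced_data(self):
        rng = np.random.default_rng(2)
        g = [list(rng.normal(m, 1.0, size=20)) for m in (0.0, 0.5, 1.0)]
        f_w, f_c = welch_anova(g).statistic, one_way_anova(g).statistic
        assert f_w == pytest.approx(f_c, rel=0.05)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DomainError, match="classic"):
            welch_anova([[1, 1, 1], [2, 3, 4]])

    def test_noninteger_denominator_df(self):
        rng = np.random.default_rng(3)
        g = [list(rng.normal(0, s, size=4)) for s in (0.5, 1.0, 4.0, 8.0)]
        res = welch_anova(g)
        assert res.df1 == 3.0
        assert res.df2 != round(res.df2)
        assert res.df2 <= sum(len(x) for x in g) - len(g)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        g = [list(rng.normal(m, s, size=n))
             for m, s, n in [(0, 1, 5), (1, 3, 8), (2, 0.5, 6)]]
        df = pd.DataFrame(
            {"y": np.concatenate(g),
             "grp": np.repeat(["a", "b", "c"], [len(x) for x in g])}
        )
        expected = pg.welch_anova(data=df, dv="y", between="grp").iloc[0]
        res = welch_anova(g)
        assert res.statistic == pytest.approx(expected["F"], rel=1e-9)
        assert res.df2 == pytest.approx(expected["ddof2"], rel=1e-9)
        assert res.pvalue == pytest.approx(expected["p_unc"], rel=1e-9)


class TestLevene:
    def test_null_pvalues_centered(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            g = [list(rng.normal(0, 1, size=10)) for _ in range(4)]
            ps.append(levene_test(g)[1])
        assert 0.35 < np.mean(ps) < 0.65

    def test_power_against_tenfold_spread(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 50
        for _ in range(reps):
            g = [list(rng.normal(0, 1, size=50)) for _ in range(3)]
            g[0] = list(rng.normal(0, 10, size=50))
            if levene_test(g)[1] < 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_constant_groups_rejected(self):
        with pytest.raises(DomainError):
            levene_test([[1, 1, 1], [2, 2, 2]])


class TestShapiro:
    def test_normal_sample_w_near_one(self):
        rng = np.random.default_rng(7)
        w, _ = shapiro_wilk(rng.normal(size=500))
        assert w > 0.98

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(8)
        hits = sum(
            shapiro_wilk(rng.exponential(size=100))[1] < 0.01 for _ in range(100)
        )
        assert hits >= 95

    def test_sample_size_limits(self):
        with pytest.raises(DomainError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(DomainError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestTukey:
    def test_equal_groups_pvalue_near_one(self):
        pairs = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pairs[0].pvalue == pytest.approx(1.0)

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(9)
        g = [list(rng.normal(0, 1, size=10)) for _ in range(2)]
        g.append(list(rng.normal(10, 1, size=10)))
        comp = route_comparison(g, ["a", "b", "c"])
        assert comp.letters["c"] not in (comp.letters["a"] + comp.letters["b"])

    def test_adjusted_p_dominates_unadjusted_pooled_t(self):
        """Tukey's studentized-range p is never smaller than the unadjusted
        pooled-variance t-test p for the same pair (multiplicity cost)."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            g = [list(rng.normal(rng.uniform(0, 1), 1, size=6)) for _ in range(4)]
            n = sum(len(x) for x in g)
            df = n - len(g)
            s2 = sum((len(x) - 1) * np.var(x, ddof=1) for x in g) / df
            for p in tukey_hsd(g):
                i, j = int(p.group_a), int(p.group_b)
                t = abs(np.mean(g[i]) - np.mean(g[j])) / np.sqrt(
                    s2 * (1 / len(g[i]) + 1 / len(g[j]))
                )
                t_p = 2 * stats.t.sf(t, df)
                assert p.pvalue >= t_p - 1e-10


class TestGamesHowell:
    def test_identical_groups_pvalue_one(self):
        pairs = games_howell([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pairs[0].pvalue == pytest.approx(1.0)

    def test_agrees_with_tukey_on_homoscedastic_balanced_data(self):
        rng = np.random.default_rng(11)
        g = [list(rng.normal(m, 1, size=20)) for m in (0.0, 0.4, 0.8)]
        gh = {(p.group_a, p.group_b): p.pvalue for p in games_howell(g)}
        tk = {(p.group_a, p.group_b): p.pvalue for p in tukey_hsd(g)}
        for pair in gh:
            assert gh[pair] == pytest.approx(tk[pair], rel=0.10, abs=0.02)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        g = [list(rng.normal(m, s, size=n))
             for m, s, n in [(0, 1, 5), (1, 3, 8), (2, 0.5, 6)]]
        df = pd.DataFrame(
            {"y": np.concatenate(g),
             "grp": np.repeat(["0", "1", "2"], [len(x) for x in g])}
        )
        expected = pg.pairwise_gameshowell(data=df, dv="y", between="grp")
        ours = {(p.group_a, p.group_b): p for p in games_howell(g)}
        for _, row in expected.iterrows():
            p = ours[(str(row["A"]), str(row["B"]))]
            assert p.pvalue == pytest.approx(row["pval"], abs=1e-6)

    def test_type_one_error_under_heteroscedasticity(self):
        """Variance ratio 100 between groups: the per-pair Welch df keeps
        the nominal 5% level approximately honest."""
        rng = np.random.default_rng(13)
        reps, hits = 400, 0
        for _ in range(reps):
            g = [list(rng.normal(0, 1, size=8)), list(rng.normal(0, 10, size=8))]
            if games_howell(g)[0].pvalue < 0.05:
                hits += 1
        assert hits / reps <= 0.075

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            games_howell([[1, 1, 1], [2, 3, 4]])


class TestRouting:
    def test_homoscedastic_data_routes_classic(self):
        rng = np.random.default_rng(14)
        g = [list(rng.normal(m, 1, size=4)) for m in (0, 1, 2, 3)]
        comp = route_comparison(g, ["10", "20", "30", ">30"])
        assert comp.route == "classic+tukey"
        assert comp.omnibus.variant == "classic"

    def test_heteroscedastic_data_routes_welch(self):
        rng = np.random.default_rng(15)
        g = [list(rng.normal(0, 0.01, size=8)) for _ in range(3)]
        g.append(list(rng.normal(0, 5, size=8)))
        comp = route_comparison(g, ["a", "b", "c", "d"])
        assert comp.route == "welch+games-howell"
        assert comp.omnibus.variant == "welch"

    def test_all_pairs_reported_for_four_sites(self, sim_chrono):
        comp = compare_metric(sim_chrono, "richness")
        assert len(comp.posthoc) == 6
        assert set(comp.letters) == set(sim_chrono.site_labels)

    def test_every_metric_computable_per_plot(self, sim_chrono):
        for metric in ("richness", "effective_species", "a_index",
                       "abundance", "dominance", "volume"):
            comp = compare_metric(sim_chrono, metric)
            assert all(len(v) == 4 for v in comp.groups.values())
            assert 0 <= comp.omnibus.pvalue <= 1

    def test_unknown_metric_rejected(self, sim_chrono):
        with pytest.raises(DomainError):
            compare_metric(sim_chrono, "biomass")
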