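import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from recortex import stats


def mixed_table(rng, n_per_group, n_within, effect=0.0):
    rows = []
    for g, n in enumerate(n_per_group):
        for s in range(n):
            for w in range(n_within):
                rows.append(
                    {
                        "subject": f"g{g}s{s}",
                        "group": f"G{g}",
                        "week": w,
                        "y": rng.normal() + effect * g * w,
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    @pytest.mark.parametrize(
        "n_per_group,n_within",
        [((14, 13, 15), 3), ((14, 15, 15), 4), ((5, 6), 3), ((4, 4, 4, 4), 2)],
    )
    def test_df_structure(self, rng, n_per_group, n_within):
        df = mixed_table(rng, n_per_group, n_within)
        res = stats.mixed_anova(df, dv="y", between="group", within="week",
                                subject="subject")
        N, g, t = sum(n_per_group), len(n_per_group), n_within
        assert res.df_pair("group*week") == ((g - 1) * (t - 1), (N - g) * (t - 1))
        assert res.df_pair("group") == (g - 1, N - g)

    def test_listwise_exclusion_of_incomplete_subjects(self, rng):
        df = mixed_table(rng, (6, 6), 3)
        df.loc[(df.subject == "g0s0") & (df.week == 1), "y"] = np.nan
        res = stats.mixed_anova(df, dv="y", between="group", within="week",
                                subject="subject")
        assert res.df_pair("group*week") == (2, 18)  # 11 complete subjects
        assert any("g0s0" in n for n in res.notes)

    def test_sqrt_transform_equals_manual(self, rng):
        df = mixed_table(rng, (5, 5), 3)
        df["y"] = df["y"] ** 2
        a = stats.mixed_anova(df, dv="y", between="group", within="week",
                              subject="subject", sqrt_transform=True)
        df2 = df.assign(y=np.sqrt(df["y"]))
        b = stats.mixed_anova(df2, dv="y", between="group", within="week",
                              subject="subject")
        pd.testing.assert_frame_equal(a.table, b.table)


class TestOneWayAnova:
    def test_df_and_identical_groups(self, rng):
        df = pd.DataFrame({"g": ["a"] * 22 + ["b"] * 22,
                           "y": np.r_[rng.normal(size=22)].tolist() * 2})
        res = stats.one_way_anova(df, "g", "y")
        assert res.df_pair("g") == (1, 42)
        assert res.effect("g")["F"] == pytest.approx(0.0, abs=1e-20)

    def test_constant_dv_flagged(self):
        df = pd.DataFrame({"g": list("aabb"), "y": 1.0})
        res = stats.one_way_anova(df, "g", "y")
        assert res.effect("g")["F"] == 0.0
        assert res.notes

    def test_type_i_error_calibration(self, rng):
        # 600-rep sanity check at alpha=0.05 (full 5000-rep suite elsewhere)
        hits = 0
        reps = 600
        for _ in range(reps):
            df = pd.DataFrame(
                {"g": np.repeat(list("abc"), 12), "y": rng.normal(size=36)}
            )
            hits += stats.one_way_anova(df, "g", "y").effect("g")["p"] < 0.05
        assert 0.03 < hits / reps < 0.07


class TestFactorialAnova:
    def test_error_df_is_n_minus_cells(self, rng):
        df = pd.DataFrame(
            {
                "a": np.repeat(list("xyz"), 30),
                "b": np.tile(np.repeat(["u", "v", "w"], 10), 3),
                "y": rng.normal(size=90),
            }
        )
        res = stats.factorial_anova(df, ["a", "b"], "y")
        assert res.df_pair("a") == (2, 81)
        assert res.df_pair("a*b") == (4, 81)

    def test_three_way_df(self, rng):
        df = pd.DataFrame(
            {
                "a": np.repeat([0, 1], 24),
                "b": np.tile(np.repeat([0, 1], 12), 2),
                "c": np.tile(np.repeat([0, 1], 6), 4),
                "y": rng.normal(size=48),
            }
        )
        res = stats.factorial_anova(df, ["a", "b", "c"], "y")
        assert res.df_pair("a") == (1, 40)
        assert res.df_pair("a*b*c") == (1, 40)

    def test_saturated_design_flagged(self, rng):
        df = pd.DataFrame(
            {"a": [0, 0, 1, 1], "b": [0, 1, 0, 1], "y": rng.normal(size=4)}
        )
        res = stats.factorial_anova(df, ["a", "b"], "y")
        assert any("saturated" in n for n in res.notes)


class TestTukey:
    def test_identical_groups_not_rejected(self, rng):
        y = rng.normal(size=15)
        df = pd.DataFrame({"g": np.repeat(list("ab"), 15), "y": np.r_[y, y]})
        out = stats.tukey_posthoc(df, "g", "y")
        assert out["p_adj"].iloc[0] > 0.9

    def test_two_groups_match_t_test_closed_form(self, rng):
        # with k=2 the studentized-range test reduces to the pooled t-test
        df = pd.DataFrame(
            {"g": np.repeat(list("ab"), 20),
             "y": np.r_[rng.normal(size=20), rng.normal(size=20) + 1.0]}
        )
        out = stats.tukey_posthoc(df, "g", "y")
        t, p = sps.ttest_ind(df[df.g == "a"].y, df[df.g == "b"].y)
        assert out["p_adj"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_large_effect_detected(self, rng):
        df = pd.DataFrame(
            {"g": np.repeat(list("ab"), 25),
             "y": np.r_[rng.normal(size=25), rng.normal(size=25) + 5.0]}
        )
        out = stats.tukey_posthoc(df, "g", "y")
        assert out["p_adj"].iloc[0] < 0.001


class TestBinomialGlm:
    def test_interaction_df(self, rng):
        rows = []
        for g in ("sham", "complete"):
            for w in (0, 4, 8, 12):
                for _ in range(40):
                    rows.append({"g": g, "w": w, "y": int(rng.uniform() < 0.3)})
        res = stats.binomial_glm_interaction(pd.DataFrame(rows), "y", "g", "w")
        assert res.df == 3   # (2-1)(4-1)
        assert not res.separation

    def test_strong_interaction_detected(self, rng):
        rows = []
        probs = {"sham": [0.1, 0.1, 0.1, 0.1], "complete": [0.1, 0.3, 0.5, 0.6]}
        for g, ps in probs.items():
            for w, p in zip((0, 4, 8, 12), ps):
                for _ in range(150):
                    rows.append({"g": g, "w": w, "y": int(rng.uniform() < p)})
        res = stats.binomial_glm_interaction(pd.DataFrame(rows), "y", "g", "w")
        assert res.p < 0.01

    def test_deterministic_outcomes_hit_separation_path(self):
        rows = []
        for g in (0, 1):
            for w in (0, 1):
                for _ in range(20):
                    rows.append({"g": g, "w": w, "y": int(g == 1 and w == 1)})
        res = stats.binomial_glm_interaction(pd.DataFrame(rows), "y", "g", "w")
        assert res.separation
        assert res.df == 1
        assert np.isfinite(res.wald_chi2)

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"g": [0, 1], "w": [0, 1], "y": [0.5, 1.0]})
        with pytest.raises(ValueError, match="binary"):
            stats.binomial_glm_interaction(df, "y", "g", "w")


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(12.0)
        res = stats.pearson_with_bisquare(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0, abs=1e-8)
        assert res.converged

    def test_null_p_values_are_uniform(self, rng):
        # 400 independent pairs; KS test against U(0,1)
        ps = []
        for _ in range(400):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps.append(stats.pearson_with_bisquare(x, y).p)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_bisquare_resists_gross_outlier(self, rng):
        x = np.arange(30.0)
        y = 2 * x + rng.normal(scale=0.5, size=30)
        y[5] += 200.0
        res = stats.pearson_with_bisquare(x, y)
        assert abs(res.slope - 2.0) < abs(res.ols_slope - 2.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.pearson_with_bisquare(np.ones(5), np.arange(5.0))


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected",
                             [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_corrected_threshold(self, alpha, m, expected):
        assert stats.bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            stats.bonferroni_alpha(0.05, 0)
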