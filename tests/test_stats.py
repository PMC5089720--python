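"""Group summaries, t tests, and the two-way ANOVA against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import clamptrace as ct
from clamptrace.stats import paired_t_test


def balanced_frame(rng, n_cell=8, effects=(0.0, 0.0, 0.0)):
    d_eff, a_eff, i_eff = effects
    rows = []
    for d in ("lean", "fat_fed"):
        for a in ("conscious", "anesthetized"):
            mu = (d_eff * (d == "fat_fed") + a_eff * (a == "anesthetized")
                  + i_eff * (d == "fat_fed") * (a == "anesthetized"))
            for _ in range(n_cell):
                rows.append((d, a, mu + rng.standard_normal()))
    return pd.DataFrame(rows, columns=["diet", "state", "y"])


class TestGroupSummaries:
    def test_mean_and_sem_by_hand(self):
        df = pd.DataFrame({"group": ["g"] * 3, "SI_P": [2.0, 4.0, 6.0]})
        (g,) = ct.summarize_groups(df, endpoints=("SI_P",))
        mean, sem = g.stats["SI_P"]
        assert mean == pytest.approx(4.0)
        assert sem == pytest.approx(2.0 / np.sqrt(3))

    def test_identical_values_zero_sem(self):
        df = pd.DataFrame({"group": ["g"] * 4, "MCR": [1.5] * 4})
        (g,) = ct.summarize_groups(df, endpoints=("MCR",))
        assert g.stats["MCR"][1] == 0.0

    def test_single_animal_sem_undefined_not_zero(self):
        df = pd.DataFrame({"group": ["g"], "MCR": [1.5]})
        (g,) = ct.summarize_groups(df, endpoints=("MCR",))
        assert np.isnan(g.stats["MCR"][1])

    def test_sem_estimates_center_on_theoretical_value(self):
        rng = np.random.default_rng(0)
        sems = [np.std(rng.normal(5.0, 1.0, 16), ddof=1) / 4.0
                for _ in range(3000)]
        assert np.mean(sems) == pytest.approx(0.25, abs=0.01)

    def test_groups_from_diet_and_state_columns(self):
        df = pd.DataFrame({"diet": ["lean", "lean", "fat_fed", "fat_fed"],
                           "state": ["conscious"] * 4,
                           "SI_P": [4.0, 5.0, 3.0, 3.5]})
        groups = {g.label: g for g in ct.summarize_groups(df, endpoints=("SI_P",))}
        assert set(groups) == {"lean:conscious", "fat_fed:conscious"}
        assert groups["lean:conscious"].n == 2


class TestStudentT:
    def test_hand_computed_pooled_t(self):
        res = ct.unpaired_t_test([1.0, 2, 3], [4.0, 5, 6])
        # pooled var = 1, SE = sqrt(2/3), t = -3/SE
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=9), rng.normal(0.5, 1.2, size=13)
        res = ct.unpaired_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_groups_null(self):
        res = ct.unpaired_t_test([3.0, 3, 3], [3.0, 3, 3])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        res = ct.unpaired_t_test([1.0, 1], [2.0, 2])
        assert res.p == 0.0 and np.isinf(res.t)

    def test_paired_t(self):
        before, after = [5.0, 6, 7, 8], [4.0, 5.5, 6, 7]
        d = np.array(before) - np.array(after)
        ref_t = d.mean() / (d.std(ddof=1) / 2.0)
        res = paired_t_test(before, after)
        assert res.t == pytest.approx(ref_t, rel=1e-12)
        assert res.df == 3


class TestTwoWayAnova:
    def test_null_identity_equal_cell_means(self):
        vals, diets, states = [], [], []
        for d in ("lean", "fat_fed"):
            for a in ("conscious", "anesthetized"):
                vals += [1.0, 2.0, 3.0]
                diets += [d] * 3
                states += [a] * 3
        tab = ct.two_way_anova(vals, diets, states, tukey=False).table
        assert tab.loc["diet", "F"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["diet", "p"] == pytest.approx(1.0)
        assert tab.loc["interaction", "p"] == pytest.approx(1.0)

    def test_pure_additive_shift_has_no_interaction(self):
        rng = np.random.default_rng(2)
        df = balanced_frame(rng, effects=(0.0, 3.0, 0.0))
        tab = ct.two_way_anova(df["y"], df["diet"], df["state"], tukey=False).table
        assert tab.loc["anesthesia", "F"] > 10.0
        assert tab.loc["anesthesia", "p"] < 0.01

    @pytest.mark.parametrize("ss_type", [2, 3])
    def test_matches_statsmodels_on_unbalanced_data(self, ss_type):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        # the cohort's 16/16/16/8 imbalance
        d = np.r_[np.repeat("lean", 32), np.repeat("fat_fed", 24)]
        s = np.r_[np.repeat("conscious", 16), np.repeat("anesthetized", 16),
                  np.repeat("conscious", 16), np.repeat("anesthetized", 8)]
        y = rng.standard_normal(56) + 0.5 * (s == "anesthetized")
        mine = ct.two_way_anova(y, d, s, ss_type=ss_type, tukey=False).table
        df = pd.DataFrame({"y": y, "d": d, "s": s})
        ref = sm.stats.anova_lm(smf.ols("y ~ C(d, Sum)*C(s, Sum)", df).fit(),
                                typ=ss_type)
        for mine_row, ref_row in zip(("diet", "anesthesia", "interaction"),
                                     ref.index[:3] if ss_type == 2
                                     else ref.index[1:4]):
            assert mine.loc[mine_row, "sum_sq"] == pytest.approx(
                ref.loc[ref_row, "sum_sq"], rel=1e-9)
            assert mine.loc[mine_row, "p"] == pytest.approx(
                ref.loc[ref_row, "PR(>F)"], rel=1e-9)

    def test_balanced_decomposition_closes(self):
        rng = np.random.default_rng(4)
        df = balanced_frame(rng, effects=(1.0, 2.0, 0.5))
        tab = ct.two_way_anova(df["y"], df["diet"], df["state"], tukey=False).table
        total = float(np.sum((df["y"] - df["y"].mean()) ** 2))
        parts = tab["sum_sq"].sum()
        assert parts == pytest.approx(total, rel=1e-9)

    def test_tukey_adjusted_p_not_below_raw_p(self):
        rng = np.random.default_rng(5)
        df = balanced_frame(rng, effects=(1.0, 1.0, 0.0))
        at = ct.two_way_anova(df["y"], df["diet"], df["state"])
        tab = at.table
        mse = tab.loc["residual", "sum_sq"] / tab.loc["residual", "df"]
        dfr = tab.loc["residual", "df"]
        cells = df.groupby(["diet", "state"])["y"]
        means = cells.mean()
        ns = cells.size()
        for _, row in at.tukey.iterrows():
            g1 = tuple(row["group1"].split(":"))
            g2 = tuple(row["group2"].split(":"))
            se = np.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
            t = abs(means[g1] - means[g2]) / se
            raw_p = 2 * sps.t.sf(t, dfr)
            assert float(row["p_adj"]) >= raw_p - 1e-9

    def test_empty_cell_drops_interaction_with_warning(self):
        y = [1.0, 2, 3, 4, 5, 6, 7, 8, 9]
        d = ["lean"] * 6 + ["fat_fed"] * 3
        s = ["conscious", "anesthetized"] * 3 + ["conscious"] * 3
        with pytest.warns(RuntimeWarning, match="interaction"):
            at = ct.two_way_anova(y, d, s, tukey=False)
        assert "interaction" not in at.table.index
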