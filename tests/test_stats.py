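"""t family, Spearman correlation, and the split-plot ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from morphstair.stats import mixed_rm_anova, spearman, t_test


class TestTTest:
    def test_identical_paired_samples(self):
        res = t_test([1, 2, 3], [1, 2, 3], paired=True)
        assert res.statistic == 0.0 or math.isnan(res.statistic)

    def test_identical_independent_samples_welch(self):
        res = t_test([1, 2, 3], [1, 2, 3], welch=True)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_hand_computed(self):
        # frozen closed-form oracle: t = -sqrt(3), df = 75/17
        res = t_test([1, 2, 3, 4], [2, 4, 6, 8], welch=True)
        assert res.statistic == pytest.approx(-math.sqrt(3))
        assert res.df == pytest.approx(75 / 17)

    def test_welch_df_never_exceeds_pooled(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 20))
            y = rng.normal(0, 3, rng.integers(3, 20))
            w = t_test(x, y, welch=True)
            assert w.df <= len(x) + len(y) - 2 + 1e-9

    def test_welch_reduces_to_student_with_equal_var_and_n(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0]  # same variance, same n
        s = t_test(x, y)
        w = t_test(x, y, welch=True)
        assert w.statistic == pytest.approx(s.statistic)
        assert w.df == pytest.approx(s.df)

    def test_one_tailed_halves_p_on_predicted_side(self):
        x = [5.0, 6.0, 7.0, 8.0]
        y = [1.0, 2.0, 3.0, 4.0]
        two = t_test(x, y)
        one = t_test(x, y, alternative="greater")
        assert one.tail == "one"
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_one_sample_against_zero(self):
        res = t_test([1.0, 2.0, 3.0])
        assert res.df == 2
        assert res.statistic == pytest.approx(2.0 / (1.0 / math.sqrt(3)))

    def test_zero_variance_reported_not_raised(self):
        res = t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], welch=True)
        assert math.isnan(res.statistic)
        assert res.note is not None

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            if t_test(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


def _midrank_spearman(x, y):
    """Independent oracle: Pearson correlation of hand-computed midranks."""

    def midranks(a):
        return [
            sum(1 for w in a if w < v) + (sum(1 for w in a if w == v) + 1) / 2
            for v in a
        ]

    rx, ry = np.array(midranks(x)), np.array(midranks(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [v**2 for v in x]).r == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x[::-1]).r == pytest.approx(-1.0)

    def test_tied_data_against_midrank_oracle(self):
        x = [1, 2, 2, 3, 4]
        y = [10, 9, 7, 8, 5]
        assert spearman(x, y).r == pytest.approx(_midrank_spearman(x, y))

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base)
        assert spearman(x, 3 * y + 7).r == pytest.approx(base)

    def test_constant_input_reported(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.r) and res.note == "constant input"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


def _mixed_data(seed=42, n_per_group=8, effect=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(2 * n_per_group):
        g = "A" if s < n_per_group else "B"
        base = rng.normal(0, 1)
        for j, c in enumerate(["c1", "c2", "c3"]):
            rows.append(
                dict(subj=s, grp=g, cond=c, y=base + effect * j + rng.normal(0, 1))
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_level_within_factor_has_vacuous_sphericity(self):
        rng = np.random.default_rng(0)
        rows = [
            dict(subj=s, cond=c, y=rng.normal())
            for s in range(10)
            for c in ["a", "b"]
        ]
        tab = mixed_rm_anova(pd.DataFrame(rows), "y", "subj", ["cond"])
        assert tab.loc["cond", "eps_hf"] == 1.0

    def test_matches_pingouin_mixed_design(self):
        pg = pytest.importorskip("pingouin")
        df = _mixed_data()
        mine = mixed_rm_anova(df, "y", "subj", ["cond"], between="grp")
        ref = pg.mixed_anova(
            data=df, dv="y", within="cond", subject="subj", between="grp"
        ).set_index("Source")
        assert mine.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"])
        assert mine.loc["cond", "F"] == pytest.approx(ref.loc["cond", "F"])
        assert mine.loc["cond * grp", "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert mine.loc["cond", "p_unc"] == pytest.approx(ref.loc["cond", "p_unc"])
        assert mine.loc["cond", "pes"] == pytest.approx(ref.loc["cond", "np2"])

    def test_epsilon_matches_pingouin_within_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        rows = []
        for s in range(12):
            base = rng.normal(0, 1)
            noise = rng.normal(0, [0.3, 1.0, 2.5, 0.5])
            for j, c in enumerate(["c1", "c2", "c3", "c4"]):
                rows.append(dict(subj=s, cond=c, y=base + 0.5 * j + noise[j]))
        df = pd.DataFrame(rows)
        mine = mixed_rm_anova(df, "y", "subj", ["cond"])
        piv = df.pivot(index="subj", columns="cond", values="y")
        assert mine.loc["cond", "eps_gg"] == pytest.approx(
            pg.epsilon(piv, correction="gg")
        )
        assert mine.loc["cond", "eps_hf"] == pytest.approx(
            pg.epsilon(piv, correction="hf")
        )

    def test_matches_statsmodels_two_within_design(self):
        anova_rm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(3)
        rows = []
        for s in range(10):
            base = rng.normal(0, 1)
            for j, c in enumerate(["c1", "c2", "c3"]):
                for k, b in enumerate(["f", "m"]):
                    rows.append(
                        dict(subj=s, cond=c, sex=b,
                             y=base + 0.4 * j - 0.3 * k + rng.normal(0, 1))
                    )
        df = pd.DataFrame(rows)
        mine = mixed_rm_anova(df, "y", "subj", ["cond", "sex"])
        ref = anova_rm.AnovaRM(df, "y", "subj", within=["cond", "sex"]).fit().anova_table
        for effect, ref_name in [("cond", "cond"), ("sex", "sex"),
                                 ("cond * sex", "cond:sex")]:
            assert mine.loc[effect, "F"] == pytest.approx(ref.loc[ref_name, "F Value"])
            assert mine.loc[effect, "df1"] == ref.loc[ref_name, "Num DF"]
            assert mine.loc[effect, "df2"] == ref.loc[ref_name, "Den DF"]

    def test_epsilon_bounds(self):
        df = _mixed_data(seed=5)
        tab = mixed_rm_anova(df, "y", "subj", ["cond"], between="grp")
        k = 3
        assert 1 / (k - 1) < tab.loc["cond", "eps_gg"] <= 1.0
        assert tab.loc["cond", "eps_hf"] <= 1.0

    def test_constant_data_reported_not_raised(self):
        rows = [dict(subj=s, cond=c, y=1.0) for s in range(6) for c in ["a", "b", "c"]]
        tab = mixed_rm_anova(pd.DataFrame(rows), "y", "subj", ["cond"])
        assert math.isnan(tab.loc["cond", "F"])

    def test_incomplete_design_rejected(self):
        df = _mixed_data().iloc[:-1]  # drop one cell
        with pytest.raises(ValueError, match="cell"):
            mixed_rm_anova(df, "y", "subj", ["cond"], between="grp")

    def test_unequal_group_sizes_rejected(self):
        df = _mixed_data()
        df = df[~((df["subj"] == 0))]
        with pytest.raises(ValueError, match="equal"):
            mixed_rm_anova(df, "y", "subj", ["cond"], between="grp")
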