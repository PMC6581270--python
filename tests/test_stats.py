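"""Normality screen, one-way ANOVA, Tukey–Kramer and Welch's t.

Reference values: the Shapiro–Wilk fixtures were evaluated once with
R 4.3's shapiro.test on the exact vectors generated here; Tukey output
is cross-checked live against statsmodels' pairwise_tukeyhsd and the
Welch test against scipy's ttest_ind, so implementation and oracle
stay on separate code paths.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ntakit import (
    DegenerateError,
    GroupCountError,
    SampleSizeError,
    nano_shapiro,
    nano_tukey,
    one_way_anova,
    welch_t,
)

# R> shapiro.test(x) on the vectors below (seeded rng, rounded to 6 dp)
R_SHAPIRO = {
    "norm": (0.9927183797, 0.9888550159),
    "expo": (0.8132760872, 0.0000017980),
}


def shapiro_vectors():
    rng = np.random.default_rng(20260926)
    return {
        "norm": rng.normal(0, 1, 50).round(6),
        "expo": rng.exponential(1.0, 50).round(6),
    }


class TestShapiro:
    def test_matches_r_reference(self):
        vecs = shapiro_vectors()
        df = pd.DataFrame({
            "g": np.repeat(["norm", "expo"], 50),
            "v": np.concatenate([vecs["norm"], vecs["expo"]]),
        })
        out = nano_shapiro(df, "g", "v").set_index("group")
        for name, (w_ref, p_ref) in R_SHAPIRO.items():
            assert out.loc[name, "W"] == pytest.approx(w_ref, abs=1e-6)
            assert out.loc[name, "p"] == pytest.approx(p_ref, abs=1e-6)
        assert out.loc["norm", "suggestion"] == "parametric"
        assert out.loc["expo", "suggestion"] == "non-parametric"
        assert out.loc["overall", "suggestion"] == "non-parametric"

    def test_all_groups_normal_suggests_parametric(self):
        v = shapiro_vectors()["norm"]
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 25),
                           "v": np.concatenate([v[:25], v[25:] + 10])})
        out = nano_shapiro(df, "g", "v")
        assert (out["suggestion"] == "parametric").all()

    def test_constant_group_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 5, "v": [2.0] * 5})
        with pytest.raises(DegenerateError):
            nano_shapiro(df, "g", "v")

    def test_too_small_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a"], "v": [1.0, 2.0]})
        with pytest.raises(SampleSizeError):
            nano_shapiro(df, "g", "v")


class TestAnova:
    def test_hand_computed_decomposition(self):
        df = pd.DataFrame({"g": np.repeat(list("abc"), 3),
                           "v": [1, 2, 3, 2, 3, 4, 3, 4, 5]})
        a = one_way_anova(df, "g", "v")
        assert a.ss_between == pytest.approx(6.0)
        assert a.ss_within == pytest.approx(6.0)
        assert (a.df_between, a.df_within) == (2, 6)
        assert a.F == pytest.approx(3.0)
        assert a.p == pytest.approx(float(sps.f.sf(3.0, 2, 6)), rel=1e-12)

    def test_sum_of_squares_partitions_total(self, rng):
        df = pd.DataFrame({"g": rng.choice(list("abcd"), 40),
                           "v": rng.normal(size=40)})
        a = one_way_anova(df, "g", "v")
        total = ((df["v"] - df["v"].mean()) ** 2).sum()
        assert a.ss_between + a.ss_within == pytest.approx(total, rel=1e-9)

    def test_identical_groups_give_f_zero(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 1, 2, 3]})
        a = one_way_anova(df, "g", "v")
        assert a.F == 0.0

    def test_all_constant_gives_p_one(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "v": [5.0] * 4})
        a = one_way_anova(df, "g", "v")
        assert (a.F, a.p) == (0.0, 1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 8),
                           "v": rng.normal([0] * 8 + [1] * 8, 1)})
        a = one_way_anova(df, "g", "v")
        t, _ = sps.ttest_ind(df.v[df.g == "a"], df.v[df.g == "b"], equal_var=True)
        assert a.F == pytest.approx(t * t, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(GroupCountError):
            one_way_anova(pd.DataFrame({"g": ["a"] * 3, "v": [1.0, 2, 3]}), "g", "v")

    def test_affine_invariance_of_f(self, rng):
        df = pd.DataFrame({"g": rng.choice(list("abc"), 30),
                           "v": rng.normal(size=30)})
        f1 = one_way_anova(df, "g", "v").F
        df2 = df.assign(v=-3.7 * df["v"] + 11.0)
        assert one_way_anova(df2, "g", "v").F == pytest.approx(f1, rel=1e-9)


class TestTukey:
    @staticmethod
    def _random_frame(seed, sizes=(5, 6, 7, 4)):
        rng = np.random.default_rng(seed)
        labels = [f"g{i}" for i in range(len(sizes))]
        g = np.repeat(labels, sizes)
        shift = dict(zip(labels, rng.uniform(-1, 2, len(sizes))))
        return pd.DataFrame({"g": g,
                             "v": [shift[x] for x in g] + rng.normal(0, 1, len(g))})

    def test_pair_count(self, rng):
        df = pd.DataFrame({"g": np.repeat([f"g{i}" for i in range(6)], 4),
                           "v": rng.normal(size=24)})
        assert len(nano_tukey(df, "g", "v")) == 15

    def test_null_means_give_high_adjusted_p(self):
        df = pd.DataFrame({"g": np.repeat(list("abc"), 4),
                           "v": [1, 2, 3, 4] * 3})
        out = nano_tukey(df, "g", "v")
        assert (out["p_adj"] >= 0.99).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self._random_frame(seed)
        out = nano_tukey(df, "g", "v")
        ref = pairwise_tukeyhsd(df["v"], df["g"])
        assert np.allclose(out["diff"], ref.meandiffs, atol=1e-6)
        assert np.allclose(out["p_adj"], ref.pvalues, atol=1e-6)
        assert np.allclose(out[["ci_low", "ci_high"]], ref.confint, atol=1e-6)

    def test_interval_brackets_difference(self):
        df = self._random_frame(9)
        out = nano_tukey(df, "g", "v")
        assert ((out["ci_low"] <= out["diff"]) & (out["diff"] <= out["ci_high"])).all()

    def test_label_swap_negates_difference(self):
        df = self._random_frame(5, sizes=(6, 6))
        out = nano_tukey(df, "g", "v")
        relabel = {"g0": "z", "g1": "a"}  # reverses sort order
        df2 = df.assign(g=df["g"].map(relabel))
        out2 = nano_tukey(df2, "g", "v")
        assert out2["diff"].iloc[0] == pytest.approx(-out["diff"].iloc[0])
        assert out2["p_adj"].iloc[0] == pytest.approx(out["p_adj"].iloc[0])
        assert out2["ci_low"].iloc[0] == pytest.approx(-out["ci_high"].iloc[0])


class TestWelch:
    def test_direct_formula_example(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4,
                           "v": [1, 2, 3, 4, 2, 4, 6, 8]})
        res = welch_t(df, "g", "v")
        assert res.t == pytest.approx(-1.7321, abs=1e-4)
        assert res.df == pytest.approx(4.412, abs=1e-3)
        t_ref, p_ref = sps.ttest_ind(df.v[df.g == "a"], df.v[df.g == "b"],
                                     equal_var=False)
        assert res.t == pytest.approx(float(t_ref), rel=1e-12)
        assert res.p == pytest.approx(float(p_ref), rel=1e-12)

    def test_identical_groups(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 1, 2, 3]})
        res = welch_t(df, "g", "v")
        assert res.t == 0.0
        assert res.p == 1.0

    def test_equal_variance_equal_n_df_limit(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4,
                           "v": [1, 2, 3, 4, 11, 12, 13, 14]})
        res = welch_t(df, "g", "v")
        assert res.df == pytest.approx(6.0, rel=1e-9)  # 2n - 2

    def test_df_bounds(self, rng):
        df = pd.DataFrame({"g": np.repeat(["a", "b"], [5, 9]),
                           "v": rng.normal(scale=[1] * 5 + [4] * 9)})
        res = welch_t(df, "g", "v")
        assert min(5, 9) - 1 <= res.df <= 5 + 9 - 2

    def test_wrong_group_count(self):
        df = pd.DataFrame({"g": list("abc"), "v": [1.0, 2, 3]})
        with pytest.raises(GroupCountError):
            welch_t(df, "g", "v")
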