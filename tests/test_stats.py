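"""Factorial Type III ANOVA and the unequal-n HSD post hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from silverquant.stats import (
    AliasingError,
    factorial_anova,
    region_analysis,
    studentized_range_p,
    unequal_n_hsd,
)

from _oracles import studentized_range_sf_mc, type3_anova_oracle


def _unbalanced_dataset(rng, levels=(2, 2, 4), max_cell=6):
    """Random unbalanced full-factorial dataset with Gaussian response."""
    rows = []
    for a in range(levels[0]):
        for b in range(levels[1]):
            for c in range(levels[2]):
                for _ in range(int(rng.integers(2, max_cell))):
                    rows.append((f"a{a}", f"b{b}", f"c{c}"))
    df = pd.DataFrame(rows, columns=["rearing", "wheel", "layer"])
    df["count"] = rng.normal(10, 2, size=len(df))
    return df


class TestFactorialAnova:
    def test_one_factor_two_groups_equals_t_squared(self):
        """With a single two-level factor, the ANOVA F equals the square of
        the pooled-variance two-sample t statistic."""
        rng = np.random.default_rng(0)
        y1, y2 = rng.normal(0, 1, 11), rng.normal(0.7, 1, 7)
        df = pd.DataFrame(
            {
                "group": ["g1"] * len(y1) + ["g2"] * len(y2),
                "count": np.concatenate([y1, y2]),
            }
        )
        tab = factorial_anova(df, factors=["group"])
        t, p = sps.ttest_ind(y1, y2, equal_var=True)
        assert tab.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)
        assert tab.loc["group", "p"] == pytest.approx(p, rel=1e-10)

    def test_null_factor_has_zero_sum_of_squares(self):
        """Balanced 2x2 data in which one factor has no effect at all: its
        Type III SS is exactly zero."""
        rows = []
        for a, mean in (("a1", 10.0), ("a2", 14.0)):
            for b in ("b1", "b2"):
                for delta in (-1.0, 1.0):
                    rows.append((a, b, mean + delta))
        df = pd.DataFrame(rows, columns=["rearing", "wheel", "count"])
        tab = factorial_anova(df, factors=["rearing", "wheel"])
        assert tab.loc["wheel", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["rearing", "sum_sq"] == pytest.approx(32.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_design_matrix_oracle(self, seed):
        """Unbalanced 2x2x4: SS and F per term agree with an explicit
        sum-coded least-squares projection to 1e-8 relative tolerance."""
        rng = np.random.default_rng(seed)
        df = _unbalanced_dataset(rng)
        tab = factorial_anova(df)
        oracle = type3_anova_oracle(df, "count", ["rearing", "wheel", "layer"])
        for term in oracle.index:
            assert tab.loc[term, "sum_sq"] == pytest.approx(
                oracle.loc[term, "sum_sq"], rel=1e-8
            ), term
            if term != "Residual":
                assert tab.loc[term, "F"] == pytest.approx(
                    oracle.loc[term, "F"], rel=1e-8
                ), term

    def test_dfs_partition_total(self):
        rng = np.random.default_rng(7)
        df = _unbalanced_dataset(rng)
        tab = factorial_anova(df)
        assert tab["df"].sum() == len(df) - 1

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(8)
        df = _unbalanced_dataset(rng)
        tab1 = factorial_anova(df)
        tab2 = factorial_anova(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(tab1, tab2, rtol=1e-10)

    def test_affine_rescaling_leaves_f_unchanged(self):
        rng = np.random.default_rng(9)
        df = _unbalanced_dataset(rng)
        scaled = df.copy()
        scaled["count"] = 3.5 * scaled["count"] - 100.0
        f1 = factorial_anova(df)["F"].dropna()
        f2 = factorial_anova(scaled)["F"].dropna()
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-8)

    def test_empty_cell_raises_aliasing_error_naming_the_cell(self):
        rng = np.random.default_rng(10)
        df = _unbalanced_dataset(rng)
        df = df[~((df["rearing"] == "a1") & (df["wheel"] == "b1") & (df["layer"] == "c2"))]
        with pytest.raises(AliasingError, match="a1.*b1.*c2"):
            factorial_anova(df)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"group": ["g1"] * 5, "count": range(5)})
        with pytest.raises(ValueError, match="2 levels"):
            factorial_anova(df, factors=["group"])


class TestStudentizedRangeP:
    def test_zero_statistic_has_unit_probability(self):
        assert studentized_range_p(0.0, 4, 20) == 1.0

    def test_two_group_identity_with_t_distribution(self):
        """For k=2 the studentized range is |t|*sqrt(2), so its tail equals
        the two-sided t tail of q/sqrt(2)."""
        for q, df in [(1.0, 5), (2.5, 12), (3.5, 40)]:
            expected = 2 * sps.t.sf(q / np.sqrt(2), df)
            assert studentized_range_p(q, 2, df) == pytest.approx(expected, rel=1e-5)

    def test_monotone_decreasing_in_q(self):
        ps = [studentized_range_p(q, 4, 20) for q in (0.5, 1.5, 2.5, 3.5, 4.5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_monte_carlo_oracle(self):
        p_mc, se = studentized_range_sf_mc(3.5, 4, 20, n_draws=10**6, seed=1)
        p = studentized_range_p(3.5, 4, 20)
        assert abs(p - p_mc) < 3 * se

    @pytest.mark.parametrize("q,k,df", [(-1, 4, 20), (2, 1, 20), (2, 4, 0)])
    def test_invalid_arguments_rejected(self, q, k, df):
        with pytest.raises(ValueError):
            studentized_range_p(q, k, df)


class TestUnequalNHsd:
    def test_reduces_to_classical_tukey_for_equal_n(self):
        """With equal group sizes the Tukey-Kramer procedure must coincide
        with the classical studentized-range HSD to numerical precision."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(11)
        k, n = 4, 8
        data = rng.normal(0, 1, size=(k, n)) + np.arange(k)[:, None]
        groups = np.repeat([f"g{i}" for i in range(k)], n)
        sm = pairwise_tukeyhsd(data.ravel(), groups)
        # one-way error term
        grand = data.mean()
        ss_err = ((data - data.mean(axis=1, keepdims=True)) ** 2).sum()
        df_err = k * (n - 1)
        res = unequal_n_hsd(
            {f"g{i}": data[i].mean() for i in range(k)},
            {f"g{i}": n for i in range(k)},
            ms_error=ss_err / df_err,
            df_error=df_err,
        )
        np.testing.assert_allclose(
            res["p_adj"].to_numpy(), sm.pvalues, atol=1e-8
        )
        np.testing.assert_allclose(
            res["mean_diff"].to_numpy(), sm.meandiffs, rtol=1e-10
        )

    def test_equal_means_give_q_zero_p_one(self):
        res = unequal_n_hsd(
            {"a": 5.0, "b": 5.0}, {"a": 4, "b": 7}, ms_error=2.0, df_error=10
        )
        assert res.loc[0, "q"] == 0.0
        assert res.loc[0, "p_adj"] == 1.0

    def test_hand_computed_tukey_kramer_statistics(self):
        """Four cells with unequal n and fixed toy numbers: q must equal
        the Tukey-Kramer formula evaluated by hand."""
        means = {"a": 10.0, "b": 14.0, "c": 9.0, "d": 20.0}
        ns = {"a": 5, "b": 3, "c": 8, "d": 4}
        ms_error, df_error = 6.0, 16
        res = unequal_n_hsd(means, ns, ms_error, df_error).set_index(
            ["group1", "group2"]
        )
        for (g1, g2), row in res.iterrows():
            se = np.sqrt(ms_error / 2 * (1 / ns[g1] + 1 / ns[g2]))
            assert row["q"] == pytest.approx(abs(means[g2] - means[g1]) / se)
            assert row["p_adj"] == pytest.approx(
                studentized_range_p(row["q"], 4, df_error), rel=1e-12
            )

    def test_symmetric_in_the_pair(self):
        means = {"a": 3.0, "b": 9.0}
        ns = {"a": 4, "b": 9}
        r1 = unequal_n_hsd(means, ns, 2.0, 11)
        r2 = unequal_n_hsd(
            {"b": 9.0, "a": 3.0}, {"b": 9, "a": 4}, 2.0, 11
        )
        assert r1.loc[0, "q"] == pytest.approx(r2.loc[0, "q"])
        assert abs(r1.loc[0, "mean_diff"]) == pytest.approx(abs(r2.loc[0, "mean_diff"]))

    def test_spjotvoll_stoline_is_conservative(self):
        means = {"a": 10.0, "b": 14.0, "c": 9.0}
        ns = {"a": 3, "b": 9, "c": 6}
        tk = unequal_n_hsd(means, ns, 6.0, 15, method="tukey-kramer")
        ss = unequal_n_hsd(means, ns, 6.0, 15, method="spjotvoll-stoline")
        assert (ss["p_adj"].to_numpy() >= tk["p_adj"].to_numpy() - 1e-12).all()

    def test_invalid_error_term_rejected(self):
        with pytest.raises(ValueError):
            unequal_n_hsd({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3}, 1.0, 0)


class TestRegionAnalysis:
    def test_full_region_pipeline_on_simulated_cohort(self, zero_noise_cohort):
        from silverquant.aggregate import animal_layer_means

        am = animal_layer_means(zero_noise_cohort)
        # zero-noise data has zero residual variance; add jitter for a
        # well-posed model
        rng = np.random.default_rng(0)
        am = am.copy()
        am["mean_count"] = am["mean_count"] + rng.normal(0, 5, size=len(am))
        res = region_analysis(am, "CA1")
        assert set(res.anova.index) == {
            "rearing", "wheel", "lamina", "rearing:wheel", "rearing:lamina",
            "wheel:lamina", "rearing:wheel:lamina", "Residual",
        }
        # 4 laminae x 4 groups -> 16 cells, 120 pairs
        assert len(res.posthoc) == 16 * 15 // 2
        assert res.anova.loc["lamina", "p"] < 0.001
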