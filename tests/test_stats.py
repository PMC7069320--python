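"""Inferential layer: SMI, AICc ranking, mixed models, rank tests, contrasts.

Rank-test p-values are cross-checked against small enumeration oracles
written here, independent of the scipy route the library uses.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from camoquant import stats
from camoquant.errors import DegenerateDataError, DomainError

REL = 1e-12


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def signed_rank_exact_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = [np.array(signs) @ ranks
                 for signs in itertools.product([0, 1], repeat=n)]
    mean_w = ranks.sum() / 2
    tail = np.sum(np.abs(np.array(stats_all) - mean_w)
                  >= abs(w_obs - mean_w) - 1e-9)
    return tail / 2 ** n


def rank_sum_exact_p(a, b):
    """Two-sided exact p by enumerating all C(n, na) group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    r_obs = ranks[:na].sum()
    all_sums = [sum(ranks[list(idx)])
                for idx in itertools.combinations(range(len(pooled)), na)]
    mean_r = na * (len(pooled) + 1) / 2
    tail = np.sum(np.abs(np.array(all_sums) - mean_r)
                  >= abs(r_obs - mean_r) - 1e-9)
    return tail / len(all_sums)


# ---------------------------------------------------------------------------
# scaled mass index
# ---------------------------------------------------------------------------

class TestScaledMassIndex:
    def test_equal_svl_returns_mass(self):
        mass = np.array([3.0, 4.0, 5.0])
        svl = np.array([60.0, 60.0, 60.0])
        # exponent base is 1, so SMI is mass unchanged ...
        assert stats.scaled_mass_index(mass, svl) == pytest.approx(mass)
        # ... but the allometric slope itself is undefined
        with pytest.raises(DegenerateDataError):
            stats.sma_exponent(mass, svl)

    def test_exact_power_law_collapses_to_common_value(self):
        svl = np.linspace(45, 70, 12)
        a, b = 2e-5, 3.0
        mass = a * svl ** b
        smi = stats.scaled_mass_index(mass, svl)
        l0 = svl.mean()
        assert np.allclose(smi, a * l0 ** b, rtol=1e-9)

    def test_unit_rescaling_invariance(self, rng):
        svl = rng.uniform(45, 70, 40)
        mass = 2e-5 * svl ** 3 * np.exp(rng.normal(0, 0.1, 40))
        smi_mm = stats.scaled_mass_index(mass, svl)
        smi_cm = stats.scaled_mass_index(mass, svl / 10.0)
        # L0 follows the unit change, so SMI is unchanged
        assert np.allclose(smi_mm, smi_cm, rtol=1e-9)

    def test_sma_exponent_is_ols_over_r(self, rng):
        svl = rng.uniform(45, 70, 60)
        mass = 2e-5 * svl ** 3 * np.exp(rng.normal(0, 0.1, 60))
        lm, ls = np.log(mass), np.log(svl)
        slope = sps.linregress(ls, lm).slope
        r = sps.pearsonr(ls, lm).statistic
        assert stats.sma_exponent(mass, svl) == pytest.approx(slope / r,
                                                              rel=1e-9)


# ---------------------------------------------------------------------------
# AICc and model ranking
# ---------------------------------------------------------------------------

class TestAicc:
    def test_hand_example(self):
        assert stats.aicc(-7, 3, 10) == pytest.approx(24.0, rel=REL)

    def test_zero_parameter_limit(self):
        assert stats.aicc(-5, 0, 10) == pytest.approx(10.0, rel=REL)

    def test_large_n_approaches_aic(self):
        assert stats.aicc(-5, 3, 10 ** 9) == pytest.approx(16.0, abs=1e-6)

    def test_small_n_error(self):
        with pytest.raises(DomainError):
            stats.aicc(-5, 9, 10)


def fm(label, loglik, k, n=100):
    return stats.FittedModel(label, loglik, k, n, pd.Series(dtype=float),
                             pd.Series(dtype=float))


class TestRankModels:
    def test_single_model(self):
        mc = stats.rank_models([fm("only", -10, 2)])
        assert mc.table.loc[0, "delta_aicc"] == 0
        assert mc.table.loc[0, "weight"] == pytest.approx(1.0, rel=REL)

    def test_equal_aicc_symmetric_weights(self):
        mc = stats.rank_models([fm("a", -10, 2), fm("b", -10, 2)])
        assert mc.table["weight"].to_numpy() == pytest.approx([0.5, 0.5],
                                                              rel=REL)

    def test_delta_two_weights(self):
        # AICc difference of 2: weights exp(0), exp(-1) normalised
        m1 = fm("better", -10, 2)
        m2 = fm("worse", -11, 2)
        mc = stats.rank_models([m1, m2])
        w = 1 / (1 + math.exp(-1))
        assert mc.table["weight"].to_numpy() == pytest.approx([w, 1 - w],
                                                              rel=1e-9)
        assert mc.best == "better"

    def test_weights_sum_to_one(self):
        mc = stats.rank_models([fm(f"m{i}", -10 - i, 2 + i) for i in range(5)])
        assert mc.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (mc.table["delta_aicc"] >= 0).all()

    def test_different_n_rejected(self):
        with pytest.raises(DomainError):
            stats.rank_models([fm("a", -10, 2, 100), fm("b", -10, 2, 99)])


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

class TestFitLmm:
    def test_single_group_equals_ols(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40), "g": "only"})
        df["y"] = 1.0 + 2.0 * df["x"] + rng.normal(0, 0.5, 40)
        m = stats.fit_lmm(df, "y", ["x"], "g")
        import statsmodels.formula.api as smf
        ols = smf.ols("y ~ x", df).fit()
        assert np.allclose(m.params.to_numpy(), ols.params.to_numpy(),
                           atol=1e-6)
        assert m.group_var == 0.0

    def test_recovers_known_effects(self, rng):
        n = 300
        g = rng.integers(0, 3, n)
        x = rng.normal(size=n)
        re = np.array([-0.5, 0.0, 0.5])[g]
        df = pd.DataFrame({"x": x, "g": g,
                           "y": 2.0 + 1.5 * x + re + rng.normal(0, 1, n)})
        m = stats.fit_lmm(df, "y", ["x"], "g")
        assert abs(m.params["x"] - 1.5) < 2 * m.bse["x"] + 0.05
        assert m.group_var > 0

    def test_nesting_never_decreases_loglik(self, rng):
        n = 120
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "z": rng.normal(size=n),
                           "g": rng.integers(0, 3, n)})
        df["y"] = 1 + df["x"] + 0.3 * np.array([-1, 0, 1])[df["g"]] \
            + rng.normal(0, 1, n)
        small = stats.fit_lmm(df, "y", ["x"], "g")
        big = stats.fit_lmm(df, "y", ["x", "z"], "g")
        assert big.loglik >= small.loglik - 1e-6
        assert big.k == small.k + 1

    def test_singular_design_names_terms(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "g": "a"})
        df["x2"] = 2 * df["x"]
        df["y"] = df["x"] + rng.normal(size=30)
        with pytest.raises(DomainError, match="collinear"):
            stats.fit_lmm(df, "y", ["x", "x2"], "g")


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = stats.linear_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0, rel=REL)
        assert res.r2 == pytest.approx(1.0, rel=REL)

    def test_null_structure(self, rng):
        x = rng.normal(size=2000)
        res = stats.linear_regression(rng.normal(size=2000), x)
        assert res.r2 < 0.01

    def test_five_point_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.3])
        # closed-form normal equations computed here
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        res = stats.linear_regression(y, x)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            stats.linear_regression([1, 2, 3], [4, 4, 4])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_all_positive_n6(self):
        res = stats.paired_signed_rank([1, 2, 3, 4, 5, 6], [0] * 6)
        assert res.p == pytest.approx(0.03125, rel=REL)
        assert "exact" in res.method

    def test_all_positive_n5(self):
        res = stats.paired_signed_rank([1, 2, 3, 4, 5], [0] * 5)
        assert res.p == pytest.approx(0.0625, rel=REL)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1, 9)
            res = stats.paired_signed_rank(d, np.zeros(9))
            assert res.p == pytest.approx(signed_rank_exact_p(d), abs=1e-12)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        r1 = stats.paired_signed_rank(a, b)
        r2 = stats.paired_signed_rank(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(DegenerateDataError):
            stats.paired_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestRankSum:
    def test_extreme_separation(self):
        res = stats.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, rel=REL)  # 2 of C(6,3) orderings

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
            res = stats.rank_sum_test(a, b)
            assert res.p == pytest.approx(rank_sum_exact_p(a, b), abs=1e-12)

    def test_identical_groups(self):
        res = stats.rank_sum_test([1, 1, 1, 1], [1, 1, 1, 1])
        assert res.p > 0.9

    def test_label_swap_complementary_statistic(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        r1 = stats.rank_sum_test(a, b)
        r2 = stats.rank_sum_test(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        assert r1.statistic + r2.statistic == pytest.approx(6 * 7)

    def test_empty_group_error(self):
        with pytest.raises(DegenerateDataError):
            stats.rank_sum_test([], [1, 2])


class TestKruskalWallis:
    def test_identical_values_h_zero(self):
        res = stats.kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert res.statistic == 0 and res.p == 1

    def test_df_is_groups_minus_one(self, rng):
        vals = rng.normal(size=40)
        groups = np.repeat(["a", "b", "c", "d"], 10)
        assert stats.kruskal_wallis(vals, groups).df == 3

    def test_two_group_consistency_with_rank_sum(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        kw = stats.kruskal_wallis(np.concatenate([a, b]),
                                  ["a"] * 30 + ["b"] * 30)
        rs = stats.rank_sum_test(a, b)
        # with two groups H is the squared rank-sum z statistic; the
        # rank-sum route adds a continuity correction, hence loose rel tol
        assert kw.p == pytest.approx(rs.p, rel=0.15)

    def test_single_group_error(self):
        with pytest.raises(DegenerateDataError):
            stats.kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestPairwiseContrasts:
    def test_two_groups_equal_plain_t_test(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(1, 1, 11)
        out = stats.pairwise_contrasts(np.concatenate([a, b]),
                                       ["a"] * 14 + ["b"] * 11)
        t = sps.ttest_ind(a, b)
        assert out.loc[0, "p_adj"] == pytest.approx(t.pvalue, rel=1e-6)

    def test_three_identical_groups_not_significant(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        out = stats.pairwise_contrasts(vals, groups)
        assert (out["p_adj"] > 0.99).all()

    def test_shifted_group_detected(self, rng):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            vals = np.concatenate([r.normal(0, 1, 15), r.normal(0, 1, 15),
                                   r.normal(2.0, 1, 15)])
            groups = np.repeat(["a", "b", "c"], 15)
            out = stats.pairwise_contrasts(vals, groups).set_index(
                ["group_a", "group_b"])
            sig = out["p_adj"] < 0.05
            hits += (sig[("a", "c")] and sig[("b", "c")]
                     and not sig[("a", "b")])
        assert hits >= 36  # >= 90% of replicates at this effect size

    def test_tiny_group_flagged_and_skipped(self, rng):
        vals = np.concatenate([rng.normal(size=10), rng.normal(size=10), [5.0]])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"]
        out = stats.pairwise_contrasts(vals, groups)
        assert out.attrs["skipped"] == ["c"]
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == \
            {("a", "b")}

    def test_holm_adjustment_route(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(3, 1, 12)])
        out = stats.pairwise_contrasts(vals, ["a"] * 12 + ["b"] * 12,
                                       adjust="holm")
        assert out.loc[0, "p_adj"] < 0.01
        assert (out["method"] == "holm").all()
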