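"""Group-level statistics: ANCOVA, Quade, nonparametrics, FDR, intervals."""

import numpy as np
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
import pandas as pd
from scipy import stats as sps

from fcendo.stats import (DegenerateDesignError, ancova, ancova_many, bh_fdr,
                          chi_square_or_fisher, kruskal_wallis, mann_whitney,
                          partial_correlation, quade_ancova, reference_interval)


class TestAncova:
    def test_matches_statsmodels_anova(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 60
            group = rng.choice(["a", "b", "c"], size=n)
            cov = rng.standard_normal((n, 2))
            y = rng.standard_normal(n) + (group == "b") * 0.5 + cov[:, 0]
            res = ancova(y, group, cov)
            df = pd.DataFrame({"y": y, "g": group, "c1": cov[:, 0],
                               "c2": cov[:, 1]})
            fit = smf.ols("y ~ C(g) + c1 + c2", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert res.statistic_value == pytest.approx(tab.loc["C(g)", "F"],
                                                        abs=1e-10)
            assert res.p_raw == pytest.approx(tab.loc["C(g)", "PR(>F)"],
                                              abs=1e-10)

    def test_no_covariates_equals_one_way_anova(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            group = np.repeat(["a", "b", "c"], 12)
            y = rng.standard_normal(36)
            res = ancova(y, group)
            f, p = sps.f_oneway(y[:12], y[12:24], y[24:])
            assert res.statistic_value == pytest.approx(f, abs=1e-10)
            assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_identical_groups_f_zero(self):
        y = np.tile(np.arange(10.0), 3)
        group = np.repeat(["a", "b", "c"], 10)
        assert ancova(y, group).statistic_value == pytest.approx(0.0, abs=1e-20)

    def test_covariate_confound_is_adjusted_away(self):
        rng = np.random.default_rng(2)
        ps, fs = [], []
        for _ in range(100):
            cov = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
            y = cov.copy()  # the group difference is purely the covariate
            group = np.repeat(["a", "b"], 30)
            res = ancova(y, group, cov)
            ps.append(res.p_raw)
            fs.append(res.statistic_value)
        assert np.median(ps) > 0.5
        assert np.median(fs) == pytest.approx(0.0, abs=1e-6)

    def test_planted_shift_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            y = rng.standard_normal(90)
            y[60:] += 1.0
            group = np.repeat(["a", "b", "c"], 30)
            hits += ancova(y, group).p_raw < 0.05
        # noncentral-F power at this design is 0.982
        assert hits / n_sim == pytest.approx(0.982, abs=0.025)

    def test_pairwise_contrasts_present(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(60)
        group = np.repeat(["a", "b", "c"], 20)
        res = ancova(y, group)
        assert {r.contrast for r in res.pairwise} == \
            {"a vs b", "a vs c", "b vs c"}

    def test_singular_design_raises(self):
        y = np.arange(12.0)
        group = np.repeat(["a", "b"], 6)
        cov = (group == "b").astype(float)  # aliased with group
        with pytest.raises(DegenerateDesignError):
            ancova(y, group, cov)

    def test_ancova_many_matches_scalar(self):
        rng = np.random.default_rng(5)
        n = 50
        group = rng.choice(["x", "y", "z"], size=n)
        cov = rng.standard_normal((n, 3))
        ys = rng.standard_normal((n, 7))
        f, p, eta = ancova_many(ys, group, cov)
        for j in range(7):
            res = ancova(ys[:, j], group, cov)
            assert f[j] == pytest.approx(res.statistic_value, abs=1e-9)
            assert p[j] == pytest.approx(res.p_raw, abs=1e-9)
            assert eta[j] == pytest.approx(res.effect_size, abs=1e-9)


class TestQuade:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(45)
        group = np.repeat(["a", "b", "c"], 15)
        cov = rng.standard_normal(45)
        base = quade_ancova(y, group, cov)
        for f in (np.exp, lambda v: v ** 3, lambda v: 5 * v - 2):
            trans = quade_ancova(f(y), group, cov)
            assert trans.statistic_value == pytest.approx(
                base.statistic_value, rel=1e-12)
            assert trans.p_raw == pytest.approx(base.p_raw, rel=1e-12)

    def test_covariate_only_structure_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            cov = rng.standard_normal(45)
            y = 0.8 * cov + rng.standard_normal(45)
            group = np.repeat(["a", "b", "c"], 15)
            hits += quade_ancova(y, group, cov).p_raw < 0.05
        assert hits / n_sim <= 0.07

    def test_detects_real_group_shift(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(60)
        y[40:] += 2.0
        group = np.repeat(["a", "b", "c"], 20)
        cov = rng.standard_normal(60)
        assert quade_ancova(y, group, cov).p_raw < 1e-4


class TestNonparametrics:
    def test_kruskal_null_mean_near_k_minus_1(self):
        rng = np.random.default_rng(9)
        hs = []
        for _ in range(1000):
            y = rng.standard_normal(30)
            group = np.repeat(["a", "b", "c"], 10)
            hs.append(kruskal_wallis(y, group).statistic_value)
        assert 1.8 < np.mean(hs) < 2.2

    def test_kruskal_eta_h(self):
        y = np.arange(30.0)
        group = np.repeat(["a", "b", "c"], 10)
        res = kruskal_wallis(y, group)
        k, n = 3, 30
        assert res.effect_size == pytest.approx(
            (res.statistic_value - k + 1) / (n - k))

    def test_mann_whitney_rank_biserial(self):
        y = np.concatenate([np.arange(10.0), np.arange(10.0) + 100])
        group = np.repeat(["a", "b"], 10)
        res = mann_whitney(y, group)
        assert abs(res.effect_size) == pytest.approx(1.0)

    def test_chi_square_perfect_association(self):
        res = chi_square_or_fisher([[10, 0], [0, 10]])
        assert res.test_name == "chi_square"
        assert res.effect_size == pytest.approx(1.0)

    def test_chi_square_no_association(self):
        res = chi_square_or_fisher([[5, 5], [5, 5]])
        assert res.statistic_value == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_fisher_when_expected_below_5(self):
        res = chi_square_or_fisher([[2, 8], [3, 1]])
        assert res.test_name == "fisher_exact"
        p_ref = sps.fisher_exact([[2, 8], [3, 1]])[1]
        assert res.p_raw == pytest.approx(p_ref)


class TestFDR:
    def test_worked_example(self):
        p = [0.001, 0.011, 0.021, 0.031, 0.041]
        adj = bh_fdr(p)
        assert np.allclose(adj, [0.005, 0.0275, 0.035, 0.03875, 0.041],
                           atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        perm = rng.permutation(25)
        assert np.allclose(bh_fdr(p[perm]), adj[perm], atol=1e-15)

    def test_single_and_degenerate(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)


class TestPartialCorrelation:
    def test_reduces_to_pearson(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal((2, 50))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_shared_covariate_removed(self):
        rng = np.random.default_rng(13)
        c = rng.standard_normal(200)
        x = rng.standard_normal(200)
        y = c.copy()
        r, p = partial_correlation(x, y, c)
        assert abs(r) < 1e-10

    def test_power_at_r_half(self):
        rng = np.random.default_rng(14)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            x = rng.standard_normal(58)
            y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(58)
            hits += partial_correlation(x, y)[1] < 0.05
        assert hits / n_sim > 0.95


class TestReferenceInterval:
    def test_flagging(self):
        rng = np.random.default_rng(15)
        ri = reference_interval(rng.standard_normal(500))
        assert ri.flag(-3.0)
        assert not ri.flag(0.0)
        assert ri.lower < ri.upper

    def test_nominal_flag_rate(self):
        rng = np.random.default_rng(16)
        ri = reference_interval(rng.standard_normal(5000))
        draws = rng.standard_normal(10000)
        rate = np.mean([ri.flag(v) for v in draws])
        assert 0.015 <= rate <= 0.035   # one-sided 2.5% +/- 1%
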