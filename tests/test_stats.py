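"""Inference battery: cluster permutation, RM-ANOVA + GG, JZS Bayes
factors, robust regression, BCa bootstrap, Friedman, Holm, logit."""

import numpy as np
import pandas as pd
import pytest

from alphakit import stats


# ----------------------------------------------------- cluster permutation

class TestClusterPermutation:
    def test_identical_topographies_give_no_clusters(self, montage32):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(12, 32))
        res = stats.cluster_permutation_test(A, A, montage32, n_perm=100, seed=0)
        assert res.clusters == []
        assert np.all(res.t_obs == 0)

    def test_recovers_injected_cluster(self, montage32):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(17, 32))
        B = rng.normal(size=(17, 32))
        idx = montage32.cluster_indices("left")
        A[:, idx] += 2.0
        res = stats.cluster_permutation_test(A, B, montage32, n_perm=500, seed=1)
        best = res.clusters[0]
        assert best.p < 0.05 and best.stat > 0
        assert set(idx).issubset(set(best.channels) | set(idx))  # overlaps
        assert len(set(best.channels) & set(idx)) >= len(idx) - 1

    def test_p_values_bounded_below(self, montage32):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 32)) + 5.0
        res = stats.cluster_permutation_test(A, np.zeros_like(A), montage32,
                                             n_perm=200, seed=2)
        for c in res.clusters:
            assert c.p >= 1.0 / (res.n_perm + 1)

    def test_clusters_are_connected(self, montage32):
        nbrs = stats.triangulation_neighbors(montage32)
        rng = np.random.default_rng(3)
        A = rng.normal(size=(17, 32))
        A[:, montage32.cluster_indices("right")] -= 1.5
        res = stats.cluster_permutation_test(A, np.zeros_like(A), montage32,
                                             n_perm=100, seed=3)
        for c in res.clusters:
            if len(c.channels) > 1:
                for ch in c.channels:
                    assert any(o in nbrs[ch] for o in c.channels if o != ch)

    def test_type_one_error_quick(self, montage16):
        # coarse calibration check (the full 500-replicate version lives in
        # the acceptance suite)
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 60
        for k in range(n_rep):
            A = rng.normal(size=(12, 16))
            B = rng.normal(size=(12, 16))
            res = stats.cluster_permutation_test(A, B, montage16, n_perm=250,
                                                 seed=k)
            hits += res.min_p < 0.05
        assert hits / n_rep < 0.15


# ----------------------------------------------------------------- ANOVA

def _design_df(Y, factors, levels):
    from itertools import product
    rows = []
    cells = list(product(*levels))
    for s in range(Y.shape[0]):
        for c, cell in enumerate(cells):
            row = {"subject": s, "value": Y[s, c]}
            row.update(dict(zip(factors, cell)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_statsmodels_f_values(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(14, 12))
        df = _design_df(Y, ["h", "p", "f"], [["L", "R"], ["c", "i"],
                                             ["t", "a", "b"]])
        mine = stats.rm_anova_gg(df, within=["h", "p", "f"])
        ref = AnovaRM(df, "value", "subject", within=["h", "p", "f"]).fit()
        table = ref.anova_table
        for name, e in mine.effects.items():
            ref_name = name.replace(":", ":")
            assert e.F == pytest.approx(table.loc[ref_name, "F Value"], rel=1e-8)
            assert e.df[0] == table.loc[ref_name, "Num DF"]
            assert e.df[1] == table.loc[ref_name, "Den DF"]

    def test_gg_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(15, 4)) + np.array([0, 0.2, 0.1, 0.6])
        Y[:, 0] += 0.9 * rng.normal(size=15)     # break sphericity
        df = _design_df(Y, ["cond"], [["a", "b", "c", "d"]])
        mine = stats.rm_anova_gg(df, within=["cond"])
        ref = pg.rm_anova(data=df, dv="value", within="cond", subject="subject",
                          correction=True)
        assert mine.effects["cond"].epsilon_gg == pytest.approx(
            float(ref["eps"].iloc[0]), abs=1e-6)
        assert mine.effects["cond"].p_gg == pytest.approx(
            float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(2)
        df = _design_df(rng.normal(size=(10, 2)), ["c"], [["x", "y"]])
        res = stats.rm_anova_gg(df, within=["c"])
        assert res.effects["c"].epsilon_gg == 1.0
        assert res.effects["c"].p_gg == res.effects["c"].p

    def test_omega_p2_zero_at_f_one_and_grows_with_f(self):
        # construct data with essentially F=1 via formula check
        rng = np.random.default_rng(3)
        df = _design_df(rng.normal(size=(12, 3)), ["c"], [["x", "y", "z"]])
        res = stats.rm_anova_gg(df, within=["c"])
        e = res.effects["c"]
        expected = max(0.0, e.df[0] * (e.F - 1)
                       / (e.df[0] * (e.F - 1) + e.df[0] + e.df[1] + 1))
        assert e.omega_p2 == pytest.approx(expected)

    def test_known_effect_detected(self):
        # 2 dB within-subject shift at n=17: p < 0.001 in most replications
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(17, 1)) * 2.0
            Y = base + rng.normal(scale=0.75, size=(17, 2))
            Y[:, 1] += 2.0
            df = _design_df(Y, ["pos"], [["c", "i"]])
            res = stats.rm_anova_gg(df, within=["pos"])
            hits += res.effects["pos"].p < 0.001
        assert hits / 40 >= 0.95

    def test_missing_cells_rejected(self):
        df = _design_df(np.zeros((5, 2)), ["c"], [["x", "y"]])
        with pytest.raises(ValueError):
            stats.rm_anova_gg(df.iloc[:-1], within=["c"])


# ----------------------------------------------------------- Bayes factors

class TestJzsBayes:
    def _paired_df(self, y1, y2):
        n = y1.size
        return pd.DataFrame({"subject": np.r_[np.arange(n), np.arange(n)],
                             "cond": ["a"] * n + ["b"] * n,
                             "value": np.r_[y1, y2]})

    @pytest.mark.parametrize("shift", [0.0, 0.4, 1.0])
    def test_two_level_factor_matches_t_oracle(self, shift):
        rng = np.random.default_rng(int(shift * 10))
        base = rng.normal(0, 2, 17)
        d = rng.normal(shift, 1.0, 17)
        df = self._paired_df(base, base + d)
        res = stats.jzs_anova_bf(df, within=["cond"], n_mc=100_000, seed=7)
        eff = res.effects["cond"]
        oracle = stats.jzs_ttest_bf(d, r=0.5)
        tol = 3 * eff.mc_error_pct / 100 * oracle
        assert abs(eff.bf10 - oracle) <= max(tol, 1e-6 * oracle)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=12)
        df = self._paired_df(base, base + rng.normal(0.5, 1, 12))
        a = stats.jzs_anova_bf(df, within=["cond"], n_mc=20000, seed=1)
        df2 = df.assign(value=df.value * 123.4)
        b = stats.jzs_anova_bf(df2, within=["cond"], n_mc=20000, seed=1)
        assert a.effects["cond"].bf10 == pytest.approx(b.effects["cond"].bf10)

    def test_bf01_is_exact_inverse(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=10)
        df = self._paired_df(base, base + rng.normal(size=10))
        eff = stats.jzs_anova_bf(df, within=["cond"], n_mc=10000,
                                 seed=2).effects["cond"]
        assert eff.bf10 * eff.bf01 == pytest.approx(1.0, rel=1e-12)

    def test_null_three_level_factor_favours_h0(self):
        # pure noise: median BF10 for a 3-level factor stays below 1
        bfs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            Y = rng.normal(size=(17, 3)) + rng.normal(size=(17, 1))
            df = _design_df(Y, ["freq"], [["t", "a", "b"]])
            bfs.append(stats.jzs_anova_bf(df, within=["freq"], n_mc=20000,
                                          seed=seed).effects["freq"].bf10)
        assert np.median(bfs) < 1.0

    def test_mc_error_shrinks_with_iterations(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=15)
        df = self._paired_df(base, base + rng.normal(0.3, 1, 15))
        e1 = stats.jzs_anova_bf(df, within=["cond"], n_mc=10_000,
                                seed=3).effects["cond"].mc_error_pct
        e2 = stats.jzs_anova_bf(df, within=["cond"], n_mc=160_000,
                                seed=3).effects["cond"].mc_error_pct
        assert e2 < e1 / 2


# ------------------------------------------------------- robust regression

class TestRobustFit:
    def test_noiseless_line_equals_ols(self):
        x = np.linspace(-2, 2, 17)
        y = 1.3 * x - 0.7
        fit = stats.robust_fit(x, y, remove_outliers=False)
        assert fit.beta1 == pytest.approx(1.3, abs=1e-8)
        assert fit.beta0 == pytest.approx(-0.7, abs=1e-8)

    def test_matches_statsmodels_rlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.standard_t(3, 30) * 0.3
        fit = stats.robust_fit(x, y, remove_outliers=False)
        ref = sm.RLM(y, sm.add_constant(x),
                     M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        assert fit.beta1 == pytest.approx(ref.params[1], abs=0.03)

    def test_resists_gross_outlier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=17)
        y = 0.8 * x + 0.05 * rng.normal(size=17)
        y_out = y.copy()
        y_out[np.argmax(x)] -= 8.0
        robust = stats.robust_fit(x, y_out, remove_outliers=False).beta1
        ols = np.polyfit(x, y_out, 1)[0]
        assert abs(robust - 0.8) < 0.05
        assert abs(ols - 0.8) > 0.2

    def test_standardized_inputs_give_zero_intercept(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 0.6 * x + 0.2 * rng.normal(size=20)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = stats.robust_fit(zx, zy, remove_outliers=False)
        assert abs(fit.beta0) < 0.1

    def test_cooks_removal_drops_influential_point(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(size=16), 4.0]
        y = np.r_[0.5 * x[:16] + 0.1 * rng.normal(size=16), -3.0]
        x2, y2, removed = stats.cooks_outlier_removal(x, y)
        assert 16 in removed
        fit = stats.robust_fit(x, y)       # removal applied inside
        assert 16 in fit.outliers_removed

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.robust_fit(np.ones(10), np.arange(10.0), remove_outliers=False)


# ----------------------------------------------------------- BCa bootstrap

class TestBca:
    def test_reduces_to_percentile_for_symmetric_statistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        ci = stats.bca_bootstrap_ci(
            lambda a, axis=-1: np.mean(a, axis=axis), (x,),
            n_boot=4000, seed=1, vectorized=True)
        # manual percentile interval
        boots = np.array([rng.choice(x, x.size).mean() for _ in range(4000)])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert ci[0] == pytest.approx(lo, abs=0.02)
        assert ci[1] == pytest.approx(hi, abs=0.02)

    def test_degenerate_distribution_collapses_to_point(self):
        x = np.ones(12)
        ci = stats.bca_bootstrap_ci(lambda a, axis=-1: np.mean(a, axis=axis),
                                    (x,), n_boot=200, seed=0, vectorized=True)
        assert ci == (1.0, 1.0)

    def test_endpoints_monotone_in_level(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 17))
        y = 0.5 * x + 0.3 * y
        stat = lambda a, b, axis=-1: stats.robust_line(a, b)[1]
        ci90 = stats.bca_bootstrap_ci(stat, (x, y), n_boot=2000, level=0.90,
                                      seed=2, vectorized=True)
        ci99 = stats.bca_bootstrap_ci(stat, (x, y), n_boot=2000, level=0.99,
                                      seed=2, vectorized=True)
        assert ci99[0] <= ci90[0] and ci90[1] <= ci99[1]

    def test_equal_slopes_difference_ci_contains_zero(self):
        rng = np.random.default_rng(6)
        x1, x2 = rng.normal(size=(2, 17))
        y1 = 0.7 * x1 + 0.2 * rng.normal(size=17)
        y2 = 0.7 * x2 + 0.2 * rng.normal(size=17)
        res = stats.slope_difference_test(x1, y1, x2, y2, n_boot=2000, seed=3)
        assert res["ci"][0] <= 0.0 <= res["ci"][1]
        assert not res["reject"]


# ------------------------------------------ Friedman, logit, Holm

def test_friedman_known_small_case():
    # k=3, n=2, both subjects rank the conditions identically -> chi2 = 4
    res = stats.friedman_test(np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]))
    assert res.statistic == pytest.approx(4.0)
    assert res.df == 2


def test_friedman_all_ties():
    res = stats.friedman_test(np.ones((6, 4)))
    assert res.statistic == 0.0 and res.p == 1.0


def test_friedman_null_p_roughly_uniform():
    rng = np.random.default_rng(7)
    ps = [stats.friedman_test(rng.normal(size=(25, 3))).p for _ in range(300)]
    from scipy.stats import kstest
    assert kstest(ps, "uniform").statistic < 0.12


def test_logit_transform_values():
    assert stats.logit_transform(0.5, 20) == 0.0
    # p = 1 clipped to 1 - 1/(2n)
    assert stats.logit_transform(1.0, 20) == pytest.approx(np.log(39.0))
    with pytest.raises(ValueError):
        stats.logit_transform(1.2, 20)


def test_holm_step_down_rule():
    # {0.01, 0.04, 0.03}: only the smallest survives (0.01*3 < 0.05,
    # then 0.03*2 = 0.06 > 0.05 stops the step-down)
    reject, p_adj = stats.holm_bonferroni([0.01, 0.04, 0.03])
    assert list(reject) == [True, False, False]
    assert p_adj[0] == pytest.approx(0.03)
    assert np.all(np.diff(np.sort(p_adj)) >= -1e-12)


def test_holm_no_rejections_at_p_one():
    reject, _ = stats.holm_bonferroni([1.0, 1.0, 1.0])
    assert not reject.any()
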