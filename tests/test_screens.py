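"""Differential screens, mutation pair patterns, correlation screens,
survival statistics, Cox regression, maximally selected cutpoints."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pathsub as ps
from pathsub.screens import logrank_two_group


class TestDegOneVsRest:
    def test_planted_fold_change_block_recovered(self):
        c = ps.make_cohort(90, 200, 3, effect=3.0, seed=30)
        degs = ps.deg_one_vs_rest(c.expression, c.labels)
        for s, block in c.marker_blocks.items():
            flagged = set(degs[s][degs[s]["flagged"]].index)
            assert len(set(block) & flagged) / len(block) >= 0.8

    def test_identical_groups_empty(self, rng):
        expr = pd.DataFrame(rng.lognormal(size=(50, 20)),
                            columns=[f"s{i}" for i in range(20)])
        expr = pd.concat([expr, expr.add_suffix("_b")], axis=1)
        labels = pd.Series([1] * 20 + [2] * 20, index=expr.columns)
        degs = ps.deg_one_vs_rest(expr, labels)
        assert not degs[1]["flagged"].any()

    def test_small_subtype_skipped_with_warning(self, rng):
        expr = pd.DataFrame(rng.lognormal(size=(10, 12)),
                            columns=[f"s{i}" for i in range(12)])
        labels = pd.Series([1] * 10 + [2] * 2, index=expr.columns)
        with pytest.warns(UserWarning, match="fewer than 3"):
            degs = ps.deg_one_vs_rest(expr, labels)
        assert 2 not in degs


class TestAnovaScreen:
    def test_null_p_values_uniform(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 60)),
                         columns=[f"s{i}" for i in range(60)])
        labels = pd.Series(np.repeat([1, 2, 3], 20), index=X.columns)
        res = ps.anova_screen(X, labels)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_shifted_group_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 60)),
                         columns=[f"s{i}" for i in range(60)])
        labels = pd.Series(np.repeat([1, 2, 3], 20), index=X.columns)
        X.loc[2, labels == 3] += 5.0
        res = ps.anova_screen(X, labels)
        assert res.loc[2, "flagged"]

    def test_f_equals_t_squared_for_two_groups(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 40)),
                         columns=[f"s{i}" for i in range(40)])
        labels = pd.Series(np.repeat([1, 2], 20), index=X.columns)
        res = ps.anova_screen(X, labels)
        t, _ = stats.ttest_ind(X.loc[:, labels == 1], X.loc[:, labels == 2],
                               axis=1)                       # pooled-variance t
        np.testing.assert_allclose(res["F"], t**2, rtol=1e-10)

    def test_degenerate_rows_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 30)),
                         columns=[f"s{i}" for i in range(30)])
        labels = pd.Series(np.repeat([1, 2, 3], 10), index=X.columns)
        X.loc[0] = labels.to_numpy(dtype=float)   # zero within-group variance
        X.loc[1] = 7.0                            # globally constant
        res = ps.anova_screen(X, labels)
        assert res.loc[0, "degenerate"] and res.loc[0, "p"] == 0.0
        assert res.loc[1, "degenerate"] and np.isnan(res.loc[1, "p"])


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisherPairPatterns:
    def test_identical_columns_co_occur(self):
        col = np.zeros(50, dtype=bool)
        col[:10] = True
        B = pd.DataFrame([col, col], index=["g1", "g2"])
        res = ps.fisher_pair_patterns(B)
        row = res.iloc[0]
        assert np.isinf(row["odds_ratio"])
        assert row["direction"] == "co-occurrence"
        assert row["p"] < 0.001

    def test_disjoint_columns_exclusive_exact_p(self):
        g1 = np.array([True] * 5 + [False] * 5)
        B = pd.DataFrame([g1, ~g1], index=["g1", "g2"])
        res = ps.fisher_pair_patterns(B)
        # table (a,b,c,d) = (0,5,5,0): two-sided p by enumeration = 2/C(10,5)
        assert res.iloc[0]["p"] == pytest.approx(fisher_oracle(0, 5, 5, 0))
        assert res.iloc[0]["p"] == pytest.approx(2 / 252)
        assert res.iloc[0]["direction"] == "exclusivity"

    def test_matches_hypergeometric_oracle_on_random_tables(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 8, size=4)
            n = a + b + c + d
            if n == 0 or a + b in (0, n) or a + c in (0, n):
                continue
            g1 = np.array([True] * (a + b) + [False] * (c + d))
            g2 = np.array([True] * a + [False] * b + [True] * c + [False] * d)
            B = pd.DataFrame([g1, g2], index=["g1", "g2"])
            res = ps.fisher_pair_patterns(B)
            assert res.iloc[0]["p"] == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-9)

    def test_uninformative_genes_skipped(self, rng):
        B = pd.DataFrame([np.ones(10, dtype=bool),
                          np.zeros(10, dtype=bool),
                          rng.random(10) < 0.5,
                          rng.random(10) < 0.5],
                         index=["all", "none", "a", "b"])
        res = ps.fisher_pair_patterns(B)
        assert set(res.attrs["skipped"]) == {"all", "none"}
        assert len(res) == 1


class TestCorrelationScreen:
    def test_perfect_and_sign_modes(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(30)])
        Y = pd.DataFrame({"a": X.loc["a"], "b": -X.loc["b"],
                          "c": rng.normal(size=30)}).T
        pos = ps.correlation_screen(X, Y, pairing="matched", sign="positive")
        ab = pos.set_index("feature_x")
        assert ab.loc["a", "flagged"]
        assert not ab.loc["b", "flagged"]
        absolute = ps.correlation_screen(X, Y, pairing="matched", sign="absolute")
        assert absolute.set_index("feature_x").loc["b", "flagged"]

    def test_all_pairs_mode_shape(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 20)), index=["x1", "x2", "x3"],
                         columns=[f"s{i}" for i in range(20)])
        Y = pd.DataFrame(rng.normal(size=(2, 20)), index=["y1", "y2"],
                         columns=X.columns)
        res = ps.correlation_screen(X, Y, pairing="all")
        assert len(res) == 6

    def test_too_few_shared_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(2, 5)), columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="shared samples"):
            ps.correlation_screen(X, X, pairing="matched")


class TestSurvivalCompare:
    def test_identical_groups_null(self, exp_survival):
        surv, _ = exp_survival
        dup = pd.concat([surv, surv.set_index(surv.index + "_b")])
        groups = pd.Series(["x"] * 200 + ["y"] * 200, index=dup.index)
        res = ps.survival_compare(dup, groups)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0, abs=1e-6)

    def test_distinct_hazards_detected(self, exp_survival):
        surv, groups = exp_survival
        res = ps.survival_compare(surv, groups)
        assert res["p"] < 0.001
        assert res["median_survival"]["a"] > res["median_survival"]["b"]

    def test_km_starts_at_one_and_matches_empirical_sf(self, exp_survival):
        surv, groups = exp_survival
        res = ps.survival_compare(surv, groups)
        curve = res["curves"]["a"]
        assert curve.iloc[0, 0] == pytest.approx(1.0)
        t_sorted = np.sort(surv[groups == "a"]["time"].to_numpy())
        # uncensored KM == empirical survival function
        for q in [0.25, 0.5, 0.75]:
            t_q = np.quantile(t_sorted, q)
            km_val = curve[curve.index <= t_q].iloc[-1, 0]
            emp = (t_sorted > t_q).mean()
            assert km_val == pytest.approx(emp, abs=1.5 / len(t_sorted))


class TestCoxUnivariate:
    def test_matches_lifelines_on_continuous_data(self, rng):
        from lifelines import CoxPHFitter
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.01 * np.exp(0.5 * x)))
        cns = rng.uniform(0, 250, size=n)
        surv = pd.DataFrame({"time": np.minimum(t, cns),
                             "event": (t <= cns).astype(int)},
                            index=[f"s{i}" for i in range(n)])
        mine = ps.cox_univariate(surv, pd.Series(x, index=surv.index))
        ll = CoxPHFitter().fit(
            pd.DataFrame({"t": surv["time"], "e": surv["event"], "x": x}),
            "t", "e")
        assert mine["beta"] == pytest.approx(float(ll.params_["x"]), abs=1e-6)
        assert mine["se"] == pytest.approx(float(ll.standard_errors_["x"]), abs=1e-6)

    def test_score_test_equals_logrank_for_binary_covariate(self, exp_survival):
        surv, groups = exp_survival
        x = (groups == "b").astype(float)
        res = ps.cox_univariate(surv, x)
        lr = logrank_two_group(surv["time"], surv["event"], x.astype(bool))
        assert res["score_chi2"] == pytest.approx(lr, rel=1e-9)

    def test_constant_covariate_rejected(self, exp_survival):
        surv, _ = exp_survival
        with pytest.raises(ValueError, match="no variation"):
            ps.cox_univariate(surv, pd.Series(1.0, index=surv.index))

    def test_null_covariate_ci_covers_one(self):
        gen = np.random.default_rng(2)
        cover = 0
        reps = 40
        for _ in range(reps):
            t = gen.exponential(100, size=120)
            surv = pd.DataFrame({"time": t, "event": 1},
                                index=[f"s{i}" for i in range(120)])
            res = ps.cox_univariate(surv, pd.Series(gen.normal(size=120),
                                                    index=surv.index))
            cover += res["ci_lower"] <= 1.0 <= res["ci_upper"]
        assert cover / reps >= 0.85


class TestLogrankTwoGroup:
    def test_matches_lifelines(self, exp_survival):
        from lifelines.statistics import logrank_test
        surv, groups = exp_survival
        g = (groups == "b").to_numpy()
        mine = logrank_two_group(surv["time"].to_numpy(),
                                 surv["event"].to_numpy(), g)
        ll = logrank_test(surv["time"][~g], surv["time"][g],
                          surv["event"][~g], surv["event"][g])
        assert mine == pytest.approx(float(ll.test_statistic), rel=1e-9)


class TestMaxstat:
    def test_hazard_step_at_median_recovered(self):
        gen = np.random.default_rng(3)
        n = 120
        score = gen.normal(size=n)
        med = np.median(score)
        h = np.where(score > med, 0.03, 0.005)
        surv = pd.DataFrame({"time": gen.exponential(1 / h), "event": 1},
                            index=[f"s{i}" for i in range(n)])
        res = ps.maxstat_cutpoint(surv, pd.Series(score, index=surv.index),
                                  n_perm=50, seed=0)
        ranks = np.sort(score)
        pos = np.searchsorted(ranks, res["cutpoint"])
        med_pos = np.searchsorted(ranks, med)
        assert abs(pos - med_pos) <= 2
        assert res["p_permutation"] <= 0.05

    def test_two_distinct_values_single_candidate(self):
        surv = pd.DataFrame({"time": [1.0, 2, 3, 4, 5, 6], "event": 1},
                            index=list("abcdef"))
        score = pd.Series([0, 0, 0, 1, 1, 1.0], index=surv.index)
        res = ps.maxstat_cutpoint(surv, score, n_perm=20, seed=0)
        assert len(res["scan"]) == 1
        assert res["cutpoint"] == pytest.approx(0.5)

    def test_degenerate_score_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2, 3], "event": 1}, index=list("abc"))
        with pytest.raises(ValueError, match="distinct"):
            ps.maxstat_cutpoint(surv, pd.Series(1.0, index=surv.index))

    def test_min_group_frac_respected(self):
        gen = np.random.default_rng(4)
        surv = pd.DataFrame({"time": gen.exponential(100, 40), "event": 1},
                            index=[f"s{i}" for i in range(40)])
        score = pd.Series(gen.normal(size=40), index=surv.index)
        res = ps.maxstat_cutpoint(surv, score, min_group_frac=0.25, n_perm=10,
                                  seed=0)
        for c in res["scan"]["cutpoint"]:
            high = (score > c).sum()
            assert 10 <= high <= 30
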