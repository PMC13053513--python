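import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cvikit.stats import (
    ModelSpec,
    apparent_auc,
    auc_lpocv,
    bootstrap_auc,
    fit_logistic,
    group_compare,
    km_logrank,
    shapley_delta_auc,
    youden_cutoff,
)

from _oracles import logistic_fit_oracle, logrank_oracle, lpocv_auc_oracle, youden_oracle


def toy_df(X, y, names=None):
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["culprit"] = np.asarray(y, float)
    return df


class TestFitLogistic:
    def test_coefficients_match_independent_optimizer(self):
        # interleaved classes keep the optimum finite and well-conditioned
        X = np.array([[-1.0, 0.3], [-0.8, -0.2], [0.5, -1.0],
                      [0.4, 0.9], [1.2, 0.1], [1.0, -0.5]])
        y = np.array([0, 1, 0, 1, 0, 1], float)
        scorer = fit_logistic(toy_df(X, y), ModelSpec(features=("f0", "f1")))
        beta_orc, _, _ = logistic_fit_oracle(X, y)
        assert np.max(np.abs(scorer.beta - beta_orc)) < 1e-6

    def test_separated_feature_ranks_positives_above_negatives(self):
        X = np.arange(8.0)
        y = (X >= 4).astype(float)
        df = toy_df(X, y)
        scorer = fit_logistic(df, ModelSpec(features=("f0",)))
        s = scorer.decision(df[["f0"]].to_numpy())
        assert s[y == 1].min() > s[y == 0].max()

    def test_affine_transform_preserves_ranking(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=20)
        y = rng.integers(0, 2, 20).astype(float)
        df1 = toy_df(X, y)
        df2 = toy_df(3.7 * X - 11.0, y)
        spec = ModelSpec(features=("f0",))
        s1 = fit_logistic(df1, spec).decision(df1[["f0"]].to_numpy())
        s2 = fit_logistic(df2, spec).decision(df2[["f0"]].to_numpy())
        assert np.array_equal(np.argsort(s1), np.argsort(s2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(toy_df(np.arange(5.0), np.ones(5)), ModelSpec(features=("f0",)))


class TestLpocv:
    def test_perfectly_separating_feature(self):
        X = np.arange(8.0)
        y = (X >= 4).astype(float)
        res = auc_lpocv(toy_df(X, y), ModelSpec(features=("f0",)))
        assert res.auc == 1.0
        assert res.n_pairs == 16

    def test_matches_brute_force_enumeration(self):
        for trial in range(8):
            rng = np.random.default_rng(trial + 10)
            n = int(rng.integers(8, 18))
            X = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, n).astype(float)
            if y.sum() < 2 or (1 - y).sum() < 2:
                continue
            mine = auc_lpocv(toy_df(X, y), ModelSpec(features=("f0", "f1"))).auc
            brute = lpocv_auc_oracle(X, y)
            assert mine == brute

    def test_null_feature_near_chance(self):
        # label-independent feature: mean LPOCV AUC close to 0.5
        # (per-cohort AUC sd is ~0.14, so the band reflects 60 Monte-Carlo reps)
        aucs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=100)
            y = rng.integers(0, 2, 100).astype(float)
            aucs.append(auc_lpocv(toy_df(X, y), ModelSpec(features=("f0",))).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.04)

    def test_degenerate_training_sets_skipped(self):
        X = np.arange(5.0)
        y = np.array([1, 0, 0, 0, 0], float)  # single positive
        res = auc_lpocv(toy_df(X, y), ModelSpec(features=("f0",)))
        assert np.isnan(res.auc)
        assert res.n_skipped == 4

    def test_affine_invariance_of_auc(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=30)
        y = rng.integers(0, 2, 30).astype(float)
        spec = ModelSpec(features=("f0",))
        a1 = auc_lpocv(toy_df(X, y), spec).auc
        a2 = auc_lpocv(toy_df(0.5 * X + 7.0, y), spec).auc
        assert a1 == a2


class TestShapley:
    @pytest.fixture
    def cohort3(self):
        rng = np.random.default_rng(8)
        n = 40
        X = rng.normal(size=(n, 3))
        logit = 1.5 * X[:, 0] + 0.7 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return toy_df(X, y, names=["a", "b", "c"])

    def test_single_feature_is_auc_minus_half(self, cohort3):
        phi = shapley_delta_auc(cohort3, ["a"])
        assert phi["a"] == pytest.approx(apparent_auc(cohort3, ModelSpec(features=("a",))) - 0.5, abs=1e-12)

    def test_efficiency_axiom(self, cohort3):
        feats = ["a", "b", "c"]
        phi = shapley_delta_auc(cohort3, feats)
        total = apparent_auc(cohort3, ModelSpec(features=tuple(feats)))
        assert sum(phi.values()) == pytest.approx(total - 0.5, abs=1e-10)

    def test_symmetry_for_duplicated_feature(self, cohort3):
        df = cohort3.copy()
        df["a2"] = df["a"]
        phi = shapley_delta_auc(df, ["a", "a2", "b"])
        assert phi["a"] == pytest.approx(phi["a2"], abs=1e-10)

    def test_matches_direct_subset_enumeration(self, cohort3):
        feats = ["a", "b", "c"]
        phi = shapley_delta_auc(cohort3, feats)
        # independent enumeration of all 8 subsets with hand-coded weights
        from itertools import combinations

        def v(S):
            return 0.5 if not S else apparent_auc(cohort3, ModelSpec(features=tuple(sorted(S))))

        from math import factorial

        k = 3
        for f in feats:
            others = [g for g in feats if g != f]
            expect = 0.0
            for r in range(3):
                for S in combinations(others, r):
                    w = factorial(len(S)) * factorial(k - len(S) - 1) / factorial(k)
                    expect += w * (v(set(S) | {f}) - v(set(S)))
            assert phi[f] == pytest.approx(expect, abs=1e-12)

    def test_monte_carlo_converges_to_exact(self, cohort3):
        df = cohort3.copy()
        df["d"] = np.random.default_rng(3).normal(size=len(df))
        feats = ["a", "b", "c", "d"]
        exact = shapley_delta_auc(df, feats)
        mc = shapley_delta_auc(df, feats, mc_samples=400, seed=11)
        for f in feats:
            assert mc[f] == pytest.approx(exact[f], abs=0.02)

    def test_mc_requires_samples_and_seed(self, cohort3):
        with pytest.raises(ValueError):
            shapley_delta_auc(cohort3, [f"x{i}" for i in range(15)])


class TestBootstrap:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(12)
        n = 80
        X = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X))).astype(float)
        return toy_df(X, y)

    def test_deterministic_given_seed(self, cohort):
        spec = ModelSpec(features=("f0",))
        r1 = bootstrap_auc(cohort, [spec], n_reps=10, seed=5)[0]
        r2 = bootstrap_auc(cohort, [spec], n_reps=10, seed=5)[0]
        assert np.array_equal(r1.replicates, r2.replicates)

    def test_single_replicate(self, cohort):
        r = bootstrap_auc(cohort, [ModelSpec(features=("f0",))], n_reps=1, seed=5)[0]
        assert r.replicates.shape == (1,)

    def test_perfect_separation_degenerate_ci(self):
        X = np.arange(20.0)
        y = (X >= 10).astype(float)
        r = bootstrap_auc(toy_df(X, y), [ModelSpec(features=("f0",))], n_reps=50, seed=1)[0]
        assert r.ci_low == pytest.approx(1.0, abs=1e-12)
        assert r.ci_high == pytest.approx(1.0, abs=1e-12)

    def test_ci_narrows_with_sample_size(self):
        widths = {}
        for n in (100, 1000):
            rng = np.random.default_rng(2)
            X = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-X))).astype(float)
            r = bootstrap_auc(toy_df(X, y), [ModelSpec(features=("f0",))], n_reps=200, seed=3)[0]
            widths[n] = r.ci_high - r.ci_low
        assert widths[1000] < widths[100]

    def test_replicates_paired_across_models(self, cohort):
        cohort = cohort.copy()
        cohort["f1"] = cohort["f0"]  # identical feature -> identical replicate AUCs
        specs = [ModelSpec(features=("f0",)), ModelSpec(features=("f1",))]
        r = bootstrap_auc(cohort, specs, n_reps=20, seed=7)
        assert np.allclose(r[0].replicates, r[1].replicates)


class TestYouden:
    def test_perfect_separation(self):
        scores = np.arange(10.0)
        labels = (scores >= 5).astype(float)
        res = youden_cutoff(scores, labels)
        assert res.j == pytest.approx(1.0)
        assert 4.0 < res.threshold < 5.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=6)
        labels = np.array([0, 1, 0, 1, 1, 0], float)
        res = youden_cutoff(scores, labels)
        t, sens, spec, j = youden_oracle(scores, labels)
        assert res.threshold == pytest.approx(t)
        assert res.j == pytest.approx(j)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(7)
        js = []
        for _ in range(20):
            scores = rng.normal(size=400)
            labels = rng.integers(0, 2, 400).astype(float)
            js.append(youden_cutoff(scores, labels).j)
        assert np.mean(js) < 0.12  # max-statistic bias keeps J small but positive

    def test_constant_scores_flagged(self):
        res = youden_cutoff(np.ones(10), np.array([0, 1] * 5, float))
        assert not res.defined
        assert res.j == 0.0


class TestKmLogrank:
    def test_identical_groups_null(self):
        t = np.array([3.0, 5.0, 7.0, 9.0] * 2)
        e = np.ones(8)
        g = np.array([False] * 4 + [True] * 4)
        res = km_logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_censoring_reduces_to_ecdf(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 1.0, 3.0])
        e = np.ones(6)
        g = np.array([False, False, False, False, True, True])
        res = km_logrank(t, e, g)
        curve = res.curves["low"]
        tt = t[:4]
        for time, surv in zip(curve.time, curve.survival):
            if time == 0:
                continue
            assert surv == pytest.approx(np.mean(tt > time))

    def test_statistic_matches_risk_set_enumeration(self):
        t = np.array([2.0, 3.0, 3.0, 5.0, 8.0, 10.0, 12.0, 14.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1], float)
        g = np.array([False, True, False, True, False, True, False, True])
        res = km_logrank(t, e, g)
        chi2, _, _ = logrank_oracle(t, e.astype(bool), g)
        assert res.statistic == pytest.approx(chi2, rel=1e-9)
        assert res.p_value == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], [True, True])


class TestGroupCompare:
    def test_study_spotty_calcification_table(self):
        # 2x2 counts: nonculprit 29/146 flagged, culprit 26/63 flagged
        sc = np.concatenate([np.ones(29), np.zeros(117), np.ones(26), np.zeros(37)])
        culprit = np.concatenate([np.zeros(146), np.ones(63)])
        df = pd.DataFrame({"sc": sc, "culprit": culprit})
        out = group_compare(df, continuous=[], categorical=["sc"])
        p = out.loc[out.feature == "sc", "p_value"].item()
        assert round(p, 3) == 0.002  # continuity-corrected chi-squared

    def test_welch_matches_summary_statistic_computation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.5, 0.8, 63)
        b = rng.normal(0.13, 0.22, 146)
        df = pd.DataFrame({"cvi": np.concatenate([a, b]),
                           "culprit": np.concatenate([np.ones(63), np.zeros(146)])})
        out = group_compare(df, continuous=["cvi"], categorical=[])
        expect = sps.ttest_ind_from_stats(
            a.mean(), a.std(ddof=1), 63, b.mean(), b.std(ddof=1), 146, equal_var=False
        )
        row = out.loc[out.feature == "cvi"].iloc[0]
        assert row.statistic == pytest.approx(expect.statistic, rel=1e-12)
        assert row.p_value == pytest.approx(expect.pvalue, rel=1e-12)

    def test_cvi_summary_statistics_scale(self):
        # group summaries like the published ones give t ~ 3.76, p < 0.001
        res = sps.ttest_ind_from_stats(0.511, 0.790, 63, 0.131, 0.220, 146, equal_var=False)
        assert res.statistic == pytest.approx(3.76, abs=0.01)
        assert res.pvalue < 0.001

    def test_zero_variance_feature_skipped(self):
        df = pd.DataFrame({"x": np.ones(20), "culprit": [0, 1] * 10})
        out = group_compare(df, continuous=["x"], categorical=[])
        assert out.loc[out.feature == "x", "skipped"].item()

    def test_welch_type_one_error_calibrated(self):
        # equal means/variances: rejection rate near the nominal level
        rng = np.random.default_rng(13)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(size=100)
            y = np.concatenate([np.zeros(60), np.ones(40)])
            df = pd.DataFrame({"x": x, "culprit": y})
            out = group_compare(df, continuous=["x"], categorical=[])
            rejections += out.p_value.item() < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08
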