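"""Regression estimators, rank test and variance components vs. oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from explorindex import (
    huber_fit,
    icc_one_way,
    mann_whitney_u,
    ols_fit,
)

MAD_CONST = float(stats.norm.ppf(0.75))


class TestOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10, dtype=float)
        y = 2.0 * x
        fit = ols_fit(y, np.column_stack([np.ones(10), x]), names=["c", "x"])
        assert fit["x"].estimate == pytest.approx(2.0, abs=1e-12)
        assert fit["x"].std_error == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_minimization_of_rss(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, 8)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, 8)
        X = np.column_stack([np.ones(8), x])
        fit = ols_fit(y, X, names=["c", "x"])

        def rss(b0, b1):
            return float(((y - b0 - b1 * x) ** 2).sum())

        b0, b1, span = 0.0, 0.0, 8.0
        for _ in range(12):
            g0 = np.linspace(b0 - span, b0 + span, 41)
            g1 = np.linspace(b1 - span, b1 + span, 41)
            vals = np.array([[rss(a, b) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            b0, b1 = g0[i], g1[j]
            span /= 8
        assert fit["c"].estimate == pytest.approx(b0, abs=1e-3)
        assert fit["x"].estimate == pytest.approx(b1, abs=1e-3)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(2)
        n = 10_000
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        fit = ols_fit(y, np.column_stack([np.ones(n), x]), names=["c", "x"])
        assert fit["x"].estimate == pytest.approx(0.5, abs=0.05)

    def test_rank_deficiency_names_collinear_column(self):
        x = np.arange(8, dtype=float)
        X = np.column_stack([np.ones(8), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="x[12]"):
            ols_fit(x, X, names=["c", "x1", "x2"])

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = X @ [1.0, -0.5, 2.0] + rng.normal(0, 1, 30)
        ours = ols_fit(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-10)


class TestHuber:
    @staticmethod
    def _toy_with_outlier():
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 12)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.3, 12)
        y[5] += 25.0  # one gross outlier
        return x, y

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_outlier_free_linear_data_equals_ols(self):
        # psi is linear inside |r| <= c, so an exact fit is a fixed point
        x = np.arange(10, dtype=float)
        y = 1.0 + 3.0 * x
        X = np.column_stack([np.ones(10), x])
        h = huber_fit(y, X, names=["c", "x"])
        o = ols_fit(y, X, names=["c", "x"])
        np.testing.assert_allclose(h.params, o.params, atol=1e-8)

    def test_reduces_to_ols_as_c_grows(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [1.0, 2.0] + rng.standard_t(3, 20)
        h = huber_fit(y, X, c=1e6)
        o = ols_fit(y, X)
        assert np.max(np.abs(h.params - o.params)) < 1e-6

    def test_matches_brute_force_objective_minimization(self):
        # oracle independent of the IRLS path: alternate (a) nested-grid
        # minimization of the convex fixed-scale Huber objective
        # sum rho((y - Xb)/s) over the two coefficients with (b) the MAD
        # scale update, until the shared fixed point is reached
        x, y = self._toy_with_outlier()
        X = np.column_stack([np.ones(12), x])
        fit = huber_fit(y, X, names=["c", "x"])

        def rho(u, c=1.345):
            a = np.abs(u)
            return np.where(a <= c, 0.5 * u**2, c * a - 0.5 * c**2)

        b0, b1 = 0.0, 0.0
        for _outer in range(25):
            r = y - b0 - b1 * x
            s = np.median(np.abs(r)) / MAD_CONST

            def objective(a0, a1):
                return float(rho((y - a0 - a1 * x) / s).sum())

            span = 12.0
            for _ in range(14):
                g0 = np.linspace(b0 - span, b0 + span, 41)
                g1 = np.linspace(b1 - span, b1 + span, 41)
                vals = np.array([[objective(a, b) for b in g1] for a in g0])
                i, j = np.unravel_index(np.argmin(vals), vals.shape)
                b0, b1 = g0[i], g1[j]
                span /= 6
        assert fit["c"].estimate == pytest.approx(b0, abs=1e-3)
        assert fit["x"].estimate == pytest.approx(b1, abs=1e-3)

    def test_downweights_the_outlier(self):
        x, y = self._toy_with_outlier()
        X = np.column_stack([np.ones(12), x])
        h = huber_fit(y, X, names=["c", "x"])
        o = ols_fit(y, X, names=["c", "x"])
        assert abs(h["x"].estimate - 0.7) < abs(o["x"].estimate - 0.7)

    def test_full_table_agrees_with_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = np.column_stack(
            [np.ones(36), rng.integers(0, 2, 36), rng.integers(0, 2, 36), rng.uniform(0.5, 13, 36)]
        )
        y = X @ [-0.5, -2.2, 2.7, -0.3] + rng.standard_t(3, 36) * 2
        ours = huber_fit(y, X)
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-7)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-7)
        assert ours.scale == pytest.approx(ref.scale, abs=1e-8)

    def test_heavy_tailed_parameter_recovery(self):
        # simulate the index model with t(3) noise at the study's sample size
        truth = np.array([0.0, -2.2, 2.7, -0.3])
        est = []
        rng = np.random.default_rng(2024)
        for _ in range(500):
            sex = rng.integers(0, 2, 36)
            par = rng.integers(0, 2, 36)
            age = rng.uniform(0.5, 13, 36)
            X = np.column_stack([np.ones(36), sex, par, age])
            y = X @ truth + rng.standard_t(3, 36)
            est.append(huber_fit(y, X, max_iter=200).params)
        est = np.array(est)
        med = np.median(est, axis=0)
        assert np.all(np.abs(med - truth) < 0.3)
        assert (est[:, 1] < 0).mean() >= 0.95  # sex sign
        assert (est[:, 2] > 0).mean() >= 0.95  # parity sign

    def test_model_fit_invariants(self, fixture_ds):
        from explorindex import compute_metrics, exploration_index
        from explorindex.pipeline import regression_design

        profiles = exploration_index(compute_metrics(fixture_ds))
        y, X, names = regression_design(fixture_ds, profiles)
        for fit in (ols_fit(y, X, names=names), huber_fit(y, X, names=names)):
            for t in fit.terms:
                assert 0.0 <= t.p_value <= 1.0
                assert t.ci_low < t.estimate < t.ci_high
                assert t.z_value == pytest.approx(t.estimate / t.std_error, abs=1e-9)


class TestMannWhitney:
    def test_complete_separation_9_vs_27(self):
        a = np.arange(100, 109, dtype=float)  # all greater
        b = np.arange(27, dtype=float)
        r = mann_whitney_u(a, b)
        assert r.u_statistic == 243.0
        assert r.u_min == 0.0
        assert r.p_value < 0.001

    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        r = mann_whitney_u(a, a.copy())
        assert r.u_statistic == r.u_min == a.size * a.size / 2

    def test_orientations_sum_to_n1n2(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 13)
        r = mann_whitney_u(a, b)
        assert r.u_statistic + r.u_min == 8 * 13

    def test_exact_p_matches_full_enumeration(self):
        # n1=3, n2=4: enumerate all C(7,3) labelings directly
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 3), rng.normal(0.5, 1, 4)
        r = mann_whitney_u(a, b)
        assert r.method == "exact"
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = r.u_statistic
        us = []
        for combo in itertools.combinations(range(7), 3):
            r1 = ranks[list(combo)].sum()
            u1 = r1 - 3 * 4 / 2
            us.append(max(u1, 12 - u1))
        us = np.array(us)
        # comparing the max orientation already pools both tails
        expected = min(1.0, float(np.mean(us >= u_obs)))
        assert r.p_value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 6)])
    def test_exact_p_matches_scipy(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a, b = rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)
        r = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approx_with_ties_matches_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(1, 7, 28).astype(float)
        r = mann_whitney_u(a, b)
        assert r.method == "normal_approx"
        assert r.tie_correction
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert r1.u_statistic == r2.u_statistic
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestICC:
    def test_zero_within_variance_gives_icc_one(self):
        vals = [1.0, 1.0, 5.0, 5.0, 9.0, 9.0]
        gids = ["a", "a", "b", "b", "c", "c"]
        assert icc_one_way(vals, gids).icc == pytest.approx(1.0)

    def test_shuffled_labels_give_near_zero_icc(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1, 1000)
        gids = rng.permutation(np.repeat(np.arange(200), 5))
        assert icc_one_way(vals, gids).icc < 0.05

    def test_reml_equals_anova_on_balanced_design(self):
        rng = np.random.default_rng(11)
        vals, gids = [], []
        for g in range(20):
            m = rng.normal(0, 1)
            for _ in range(4):
                vals.append(m + rng.normal(0, 2))
                gids.append(g)
        r = icc_one_way(vals, gids, "reml")
        a = icc_one_way(vals, gids, "anova")
        assert r.icc == pytest.approx(a.icc, abs=1e-6)
        assert r.sigma2_between == pytest.approx(a.sigma2_between, rel=1e-4, abs=1e-6)

    def test_balanced_recovery_of_icc_0_10(self):
        rng = np.random.default_rng(12)
        vals, gids = [], []
        for g in range(200):
            m = rng.normal(0, 1.0)  # sigma2_between = 1
            for _ in range(5):
                vals.append(m + rng.normal(0, 3.0))  # sigma2_within = 9
                gids.append(g)
        r = icc_one_way(vals, gids)
        assert r.icc == pytest.approx(0.10, abs=0.03)

    def test_unbalanced_reml_agrees_with_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        vals, gids = [], []
        for g in range(30):
            m = rng.normal(0, 1.2)
            for _ in range(int(rng.integers(1, 6))):
                vals.append(m + rng.normal(0, 2.0))
                gids.append(g)
        ours = icc_one_way(vals, gids)
        md = sm.MixedLM(np.asarray(vals), np.ones((len(vals), 1)), groups=np.asarray(gids))
        ref = md.fit(reml=True)
        s2b = float(np.asarray(ref.cov_re)[0, 0])
        s2w = float(ref.scale)
        assert ours.sigma2_between == pytest.approx(s2b, rel=1e-4, abs=1e-6)
        assert ours.sigma2_within == pytest.approx(s2w, rel=1e-4, abs=1e-6)

    def test_negative_component_truncates_to_zero(self):
        # groups carry no signal and few levels: ANOVA estimate often negative
        vals = [0.0, 1.0, 1.0, 0.0, 0.5, 0.5]
        gids = ["a", "a", "b", "b", "c", "c"]
        r = icc_one_way(vals, gids, "anova")
        assert r.sigma2_between >= 0.0
        assert 0.0 <= r.icc <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            icc_one_way([1.0, 2.0], ["a", "a"])
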