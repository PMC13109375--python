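import numpy as np
import pytest

import connlearn as cl
from connlearn import lassosel as lsel

from conftest import random_design


class TestLambdaPath:
    def test_hand_evaluated_toy_problem(self):
        # sum x1 y = sum x2 y = 4, n = 4 -> lambda_max = 1
        X = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1]], dtype=float)
        y = np.array([2.0, 0.0, 0.0, -2.0])
        path = cl.lambda_path(X, y, K=100)
        assert path.lambda_max == pytest.approx(1.0, abs=1e-12)

    def test_endpoints_and_log_spacing(self):
        rng = np.random.default_rng(0)
        X, y = rng.standard_normal((50, 5)), rng.standard_normal(50)
        path = cl.lambda_path(X, y, K=1000, epsilon=1e-4)
        assert path.values[0] == pytest.approx(path.lambda_max, rel=1e-12)
        assert path.values[-1] / path.values[0] == pytest.approx(1e-4, rel=1e-12)
        logs = np.log(path.values)
        assert np.allclose(np.diff(logs), logs[1] - logs[0], atol=1e-10)

    def test_homogeneity_in_y(self):
        rng = np.random.default_rng(1)
        X, y = rng.standard_normal((40, 6)), rng.standard_normal(40)
        assert cl.lambda_path(X, 2 * y, K=10).lambda_max == pytest.approx(
            2 * cl.lambda_path(X, y, K=10).lambda_max
        )

    def test_zero_outcome_rejected(self):
        X = np.random.default_rng(2).standard_normal((10, 3))
        with pytest.raises(ValueError):
            cl.lambda_path(X, np.zeros(10), K=10)


class TestLassoFit:
    def test_soft_threshold_closed_form_on_orthonormal_design(self):
        rng = np.random.default_rng(3)
        n, p = 200, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)  # X'X = n I
        y = rng.standard_normal(n)
        for lam in (0.01, 0.05, 0.2):
            beta = cl.lasso_fit(X, y, lam)
            z = X.T @ y / n
            closed = np.sign(z) * np.maximum(np.abs(z) - lam, 0)
            assert np.abs(beta - closed).max() < 1e-8

    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(4)
        X, y = rng.standard_normal((60, 10)), rng.standard_normal(60)
        lam_max = cl.lambda_path(X, y, K=5).lambda_max
        assert np.all(cl.lasso_fit(X, y, lam_max * (1 + 1e-10)) == 0)

    def test_zero_lambda_recovers_ols(self):
        rng = np.random.default_rng(5)
        X, y = rng.standard_normal((80, 6)), rng.standard_normal(80)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(cl.lasso_fit(X, y, 0.0) - ols).max() < 1e-6

    def test_matches_sklearn_on_unweighted_problem(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 10))
        y = 0.5 * X[:, 0] - 0.3 * X[:, 4] + rng.standard_normal(100)
        for lam in (0.02, 0.1, 0.5):
            ours = cl.lasso_fit(X, y, lam)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=200_000).fit(X, y).coef_
            assert np.abs(ours - ref).max() < 1e-6

    def test_kkt_on_random_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, p = rng.integers(20, 80), rng.integers(2, 15)
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            lam = float(rng.uniform(0.01, 0.5))
            w = rng.uniform(0.5, 2.0, p)
            exempt = rng.random(p) < 0.2
            beta = cl.lasso_fit(X, y, lam, penalty_exempt=exempt, penalty_weights=w)
            assert lsel.kkt_check(X, y, beta, lam, penalty_exempt=exempt,
                                  penalty_weights=w)

    def test_exempt_columns_never_shrunk(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 5))
        y = X[:, 0] + rng.standard_normal(100)
        exempt = np.array([True, False, False, False, False])
        beta = cl.lasso_fit(X, y, 10.0, penalty_exempt=exempt)
        assert beta[0] != 0
        assert np.all(beta[1:] == 0)

    def test_larger_penalty_weight_shrinks_harder(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 2))
        y = 0.5 * X.sum(axis=1) + rng.standard_normal(200)
        w = np.array([1.0, 3.0])
        beta = cl.lasso_fit(X, y, 0.1, penalty_weights=w)
        assert abs(beta[1]) < abs(beta[0])

    def test_warm_and_cold_starts_agree(self):
        rng = np.random.default_rng(10)
        X, y = rng.standard_normal((80, 12)), rng.standard_normal(80)
        path = cl.lambda_path(X, y, K=50)
        from connlearn._cd import cd_path

        G, c = X.T @ X / 80, X.T @ y / 80
        warm, _ = cd_path(G, c, path.values, np.ones(12), 1e-9, 100_000)
        for k in (0, 10, 25, 49):
            cold = cl.lasso_fit(X, y, path.values[k], tol=1e-9)
            assert np.abs(warm[k] - cold).max() < 1e-6


class TestBuildDesign:
    def test_fc_design_has_22_columns(self, planted_cohort, acquisition_design):
        assert acquisition_design.X.shape[1] == 22
        assert acquisition_design.penalty_exempt.sum() == 2
        assert acquisition_design.labels[-2:] == ["age", "sex"]

    def test_ec_design_has_42_columns_with_weights(self, planted_cohort):
        scores = cl.score_cohort(planted_cohort, "acquisition")
        d = cl.build_design(planted_cohort, "EC", "acquisition", scores)
        assert d.X.shape[1] == 42
        pen_w = d.penalty_weights[~d.penalty_exempt]
        assert pen_w.mean() == pytest.approx(1.0)
        assert pen_w.std() > 0  # posterior variances differ across edges

    def test_connectivity_columns_standardized(self, acquisition_design):
        edge_cols = acquisition_design.X[:, ~acquisition_design.penalty_exempt]
        assert np.allclose(edge_cols.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(edge_cols.std(axis=0), 1, atol=1e-10)


class TestRepeatedCV:
    def test_bookkeeping_1000_models(self, planted_cohort):
        import connlearn as cl

        scores = cl.score_cohort(planted_cohort, "acquisition")
        design = cl.build_design(planted_cohort, "FC", "acquisition", scores)
        res = cl.repeated_cv_selection(design, n_reps=100, n_folds=10, K=100, seed=0)
        assert res.n_models == 1000
        assert res.counts.max() <= 1000
        assert len(res.optimal_lambdas) == 100

    def test_seeded_determinism_and_column_order_invariance(self, rng):
        d = random_design(rng, n=50, p=8, r2=0.3)
        r1 = cl.repeated_cv_selection(d, n_reps=3, n_folds=5, K=50, seed=42)
        r2 = cl.repeated_cv_selection(d, n_reps=3, n_folds=5, K=50, seed=42)
        assert np.array_equal(r1.counts, r2.counts)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        d_perm = cl.DesignMatrix(
            X=d.X[:, perm], y=d.y, labels=[d.labels[i] for i in perm],
            penalty_exempt=d.penalty_exempt[perm],
            penalty_weights=d.penalty_weights[perm], groups=d.groups,
            paradigm=d.paradigm,
        )
        r3 = cl.repeated_cv_selection(d_perm, n_reps=3, n_folds=5, K=50, seed=42)
        by_label = dict(zip(r3.labels, r3.counts))
        assert [by_label[lab] for lab in d.labels] == list(r1.counts)

    def test_too_few_subjects_rejected(self, rng):
        d = random_design(rng, n=15, p=4)
        with pytest.raises(ValueError):
            cl.repeated_cv_selection(d, n_folds=10)


class TestBinomialSelectionTest:
    @staticmethod
    def result_with_counts(counts, n_models=1000):
        p = len(counts)
        return lsel.SelectionResult(
            labels=[f"x{i}" for i in range(p)], counts=np.asarray(counts),
            n_models=n_models, mean_nonzero_coef=np.zeros(p),
            optimal_lambdas=np.zeros(1), cv_mse=np.zeros(1),
            penalty_exempt=np.zeros(p, dtype=bool),
        )

    def test_exact_tail_values(self):
        from scipy.stats import binom

        res = self.result_with_counts([600, 500, 1000])
        res = cl.selection_binomial_test(res, p0=0.5)
        assert res.binomial_p[0] == pytest.approx(
            binom.sf(599, 1000, 0.5), rel=1e-12
        )
        assert res.binomial_p[0] == pytest.approx(1.4e-10, rel=0.05)
        assert res.binomial_p[1] == pytest.approx(0.5126, abs=0.01)
        assert res.binomial_p[2] == pytest.approx(0.5**1000, rel=1e-9)

    def test_fdr_flags_monotone_in_p(self):
        res = self.result_with_counts([900, 700, 520, 480])
        res = cl.selection_binomial_test(res, p0=0.5)
        order = np.argsort(res.binomial_p)
        flags = res.fdr_significant[order]
        assert not np.any(np.diff(flags.astype(int)) > 0)

    def test_invalid_p0(self):
        res = self.result_with_counts([10])
        with pytest.raises(ValueError):
            cl.selection_binomial_test(res, p0=0.0)


class TestSelectionCalibration:
    """Counts share the CV-optimal penalty, so under a null outcome whole
    count vectors saturate together: the binomial flags over-reject at the
    family level (a documented screening property), while the max-count
    permutation test stays family-wise calibrated."""

    CV = dict(n_reps=5, n_folds=10, K=50)

    def test_binomial_flags_overreject_on_null_families(self, rng):
        fired = 0
        n_runs = 40
        for _ in range(n_runs):
            d = random_design(rng, n=100, p=10)
            res = cl.repeated_cv_selection(d, seed=int(rng.integers(2**31)),
                                           **self.CV)
            res = cl.selection_binomial_test(res, p0=0.5)
            fired += res.fdr_significant.any()
        assert fired / n_runs > 0.15  # far above the nominal 5%

    def test_maxcount_test_family_calibrated(self, rng):
        fired = 0
        n_runs = 60
        for _ in range(n_runs):
            d = random_design(rng, n=100, p=10)
            res = cl.repeated_cv_selection(d, seed=int(rng.integers(2**31)),
                                           **self.CV)
            res = lsel.selection_maxcount_test(
                d, res, n_runs=20, seed=int(rng.integers(2**31)), **self.CV
            )
            fired += res.maxcount_significant.any()
        assert fired / n_runs <= 0.05

    def test_maxcount_pvalues_rank_planted_edges_first(self, rng):
        # the count statistic is bounded by n_models, so occasional saturated
        # null runs cap the attainable significance; the planted edges still
        # receive the smallest permutation p-values
        d = random_design(rng, n=300, p=10, r2=0.5)
        res = cl.repeated_cv_selection(d, seed=0, rule="1se", **self.CV)
        res = lsel.selection_maxcount_test(d, res, n_runs=20, seed=0,
                                           rule="1se", **self.CV)
        assert res.maxcount_p[:3].max() <= res.maxcount_p[3:].min()
        assert res.maxcount_p[:3].max() < 0.2


class TestCompanions:
    def test_ridge_limits(self, rng):
        d = random_design(rng, n=100, p=6, r2=0.4)
        from sklearn.linear_model import Ridge

        Xs = (d.X - d.X.mean(axis=0)) / d.X.std(axis=0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(100), Xs]), d.y, rcond=None)[0][1:]
        tiny = Ridge(alpha=1e-8).fit(Xs, d.y).coef_
        huge = Ridge(alpha=1e8).fit(Xs, d.y).coef_
        assert np.abs(tiny - ols).max() < 1e-4
        assert np.abs(huge).max() < 1e-4

    def test_ridge_sign_recovery_of_strong_edge(self, rng):
        hits = 0
        for i in range(40):
            d = random_design(rng, n=120, p=10, r2=0.3, k=1)
            coefs = lsel.ridge_all_edges(d, mode="ridge")
            hits += coefs.set_index("predictor").loc["x0", "coef"] > 0
        assert hits >= 38  # planted positive effect: sign recovered >= 95%

    def test_ridge_tracks_lasso_nonzeros(self, acquisition_design):
        res = cl.repeated_cv_selection(acquisition_design, n_reps=5, n_folds=10,
                                       K=100, seed=0)
        ridge = lsel.ridge_all_edges(acquisition_design, mode="ridge")
        lasso_mean = res.mean_nonzero_coef
        keep = ~np.isnan(lasso_mean) & (res.counts > res.n_models / 2)
        r = np.corrcoef(ridge.coef.to_numpy()[keep], lasso_mean[keep])[0, 1]
        assert r > 0.5


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(11)
        Q, _ = np.linalg.qr(rng.standard_normal((100, 5)))
        d = random_design(rng, n=100, p=5)
        d.X = Q
        diag = lsel.collinearity_diagnostics(d)
        assert np.allclose(diag["vif"], 1.0, atol=0.01)

    def test_known_pairwise_correlation_vif(self):
        rng = np.random.default_rng(12)
        n = 200_000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        d = random_design(rng, n=n, p=2)
        d.X = np.column_stack([x1, x2])
        diag = lsel.collinearity_diagnostics(d)
        assert np.allclose(diag["vif"], 1 / (1 - 0.81), rtol=0.02)

    def test_duplicated_column_flagged_infinite(self, rng):
        d = random_design(rng, n=50, p=3)
        d.X[:, 2] = d.X[:, 1]
        diag = lsel.collinearity_diagnostics(d)
        assert np.isinf(diag["vif"][1]) and np.isinf(diag["vif"][2])
        assert "x2" in diag["flagged"]

    def test_variance_proportions_sum_to_one(self, rng):
        d = random_design(rng, n=80, p=6)
        diag = lsel.collinearity_diagnostics(d)
        assert np.allclose(diag["variance_proportions"].sum(axis=1), 1.0)


class TestSplitHalf:
    def test_planted_effect_detected(self, rng):
        hits = 0
        for i in range(20):
            d = random_design(rng, n=400, p=10, r2=0.2)
            res = cl.split_half_mse_test(d, n_iterations=20, n_perm=2000,
                                         seed=rng.integers(2**31), K=50, cv_folds=5)
            hits += (res.p_value < 0.05) and (res.mean_difference < 0)
        assert hits >= 16

    def test_degenerate_constant_outcome_gives_p_one(self, rng):
        # shuffling a constant outcome changes nothing: every difference is 0
        d = random_design(rng, n=40, p=4)
        d.y = np.ones(40)
        res = cl.split_half_mse_test(d, n_iterations=5, n_perm=2000, seed=0)
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 40"):
            cl.split_half_mse_test(random_design(rng, n=30, p=3))
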