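import numpy as np
import pandas as pd
import pytest

import connlearn as cl
from connlearn import synthgen as sg
from connlearn import validate as val

from conftest import random_design


class TestHubResampling:
    def test_counting_is_per_endpoint(self, rng, monkeypatch):
        # force the internal selection to always flag two ACC edges
        d = random_design(rng, n=60, p=4,
                          labels=["lACC-lAMY", "lACC-lHIP", "lPFC-rCEB", "lAMY-lHIP"])

        class Fake:
            def significant_edges(self):
                return ["lACC-lAMY", "lACC-lHIP"]

        monkeypatch.setattr(val, "repeated_cv_selection",
                            lambda *a, **k: Fake())
        monkeypatch.setattr(val, "selection_binomial_test", lambda r, **k: r)
        res = val.hub_resampling(d, B=10, seed=0, n_reps=1, K=10)
        assert res.totals["ACC"] == 20
        assert res.totals["AMY"] == 10 and res.totals["HIP"] == 10
        assert res.totals["CEB"] == 0

    def test_no_significant_edges_no_flags(self, rng, monkeypatch):
        d = random_design(rng, n=60, p=4,
                          labels=["lACC-lAMY", "lACC-lHIP", "lPFC-rCEB", "lAMY-lHIP"])

        class Fake:
            def significant_edges(self):
                return []

        monkeypatch.setattr(val, "repeated_cv_selection", lambda *a, **k: Fake())
        monkeypatch.setattr(val, "selection_binomial_test", lambda r, **k: r)
        res = val.hub_resampling(d, B=10, seed=0, n_reps=1, K=10)
        assert (res.totals == 0).all()
        assert res.irr is None

    def test_planted_region_has_largest_rate(self):
        # effects planted on three ACC-involving edges: ACC should dominate
        planted = ("lACC-lAMY", "lACC-lHIP", "rACC-rPFC")
        wins = 0
        n_runs = 8
        for s in range(n_runs):
            cohort = sg.gen_cohort(
                [sg.StudyDesign("S1", "FL", "SCR", 200)],
                effect=sg.PlantedEffect(modality="FC", effect_edges=planted,
                                        coefficients=(1.0, 1.0, 1.0),
                                        target_r2=0.25),
                seed=300 + s, generate_timeseries=False,
            )
            scores = cl.score_cohort(cohort, "acquisition")
            design = cl.build_design(cohort, "FC", "acquisition", scores)
            res = cl.hub_resampling(design, B=25, seed=s, n_reps=3, K=50)
            wins += res.irr.set_index("region").irr.idxmax() == "ACC"
        assert wins >= n_runs - 1


class TestParadigmTransfer:
    def test_shared_effect_detected(self, rng):
        hits = 0
        for i in range(20):
            tr = random_design(rng, n=200, p=10, r2=0.15)
            te = random_design(rng, n=200, p=10, r2=0.15)
            res = cl.paradigm_transfer_test(tr, te, M=20, n_perm=2000,
                                            seed=rng.integers(2**31), K=50,
                                            cv_folds=5)
            hits += res.p_value < 0.05
        assert hits >= 16

    def test_all_zero_differences_give_p_one(self, rng):
        tr = random_design(rng, n=100, p=4, r2=0.3)
        te = random_design(rng, n=100, p=4)
        te.y = np.ones(100)  # constant outcome: shuffles change nothing
        res = cl.paradigm_transfer_test(tr, te, M=10, n_perm=1000, seed=0, K=20,
                                        cv_folds=5)
        assert res.mean_difference == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_overlapping_subjects_rejected(self, rng):
        tr = random_design(rng, n=50, p=4)
        te = random_design(rng, n=50, p=4)
        tr.subject_ids = np.arange(50)
        te.subject_ids = np.arange(25, 75)
        with pytest.raises(ValueError, match="share subjects"):
            cl.paradigm_transfer_test(tr, te, M=5, n_perm=1000, seed=0, K=10)


class TestLogo:
    def make_multistudy(self, rng, noise_sd, n_per=40, n_studies=4):
        n = n_per * n_studies
        X = rng.standard_normal((n, 6))
        y = X[:, 0] + 0.5 * X[:, 1] + noise_sd * rng.standard_normal(n)
        groups = np.repeat([f"S{i}" for i in range(n_studies)], n_per)
        d = random_design(rng, n=n, p=6, groups=groups)
        d.X, d.y = X, y
        return d

    def test_noiseless_shared_effect_pooled_r_one(self, rng):
        d = self.make_multistudy(rng, noise_sd=0.0)
        res = cl.logo_crossvalidation(d, ["x0", "x1"], include_covariates=False)
        assert res.pooled_r == pytest.approx(1.0, abs=1e-8)

    def test_null_outcome_r_near_zero(self, rng):
        rs = []
        for i in range(50):
            d = self.make_multistudy(rng, noise_sd=0.0)
            d.y = rng.standard_normal(d.n)
            rs.append(cl.logo_crossvalidation(d, ["x0", "x1"],
                                              include_covariates=False).pooled_r)
        # pooled out-of-fold prediction correlations carry the standard
        # negative CV bias under the null: centred slightly below zero,
        # never systematically positive
        assert -0.15 < np.mean(rs) < 0.02
        assert np.mean([abs(r) < 0.35 for r in rs]) >= 0.95

    def test_partial_effect_between_extremes(self, rng):
        full = self.make_multistudy(rng, noise_sd=0.2)
        partial = self.make_multistudy(rng, noise_sd=0.2)
        null_study = partial.groups == "S3"
        partial.y[null_study] = rng.standard_normal(null_study.sum())
        r_full = cl.logo_crossvalidation(full, ["x0", "x1"],
                                         include_covariates=False).pooled_r
        r_part = cl.logo_crossvalidation(partial, ["x0", "x1"],
                                         include_covariates=False).pooled_r
        assert r_full > r_part > 0.1

    def test_prediction_never_uses_left_out_study(self, rng):
        # corrupting a study's outcomes must not change its own predictions
        d = self.make_multistudy(rng, noise_sd=0.5)
        res = cl.logo_crossvalidation(d, ["x0"], include_covariates=False)
        d2_y = d.y.copy()
        mask = d.groups == "S0"
        d2_y[mask] += 100.0
        d2 = self.make_multistudy(rng, noise_sd=0.5)
        d2.X, d2.y, d2.groups = d.X, d2_y, d.groups
        res2 = cl.logo_crossvalidation(d2, ["x0"], include_covariates=False)
        assert np.allclose(res.predicted[mask], res2.predicted[mask])

    def test_too_few_studies_or_unknown_predictor(self, rng):
        d = self.make_multistudy(rng, 0.5, n_studies=2)
        with pytest.raises(ValueError, match=">= 3"):
            cl.logo_crossvalidation(d, ["x0"])
        d3 = self.make_multistudy(rng, 0.5)
        with pytest.raises(ValueError, match="not in design"):
            cl.logo_crossvalidation(d3, ["nope"])

    def test_fisher_z_comparison(self):
        out = val.compare_correlations(0.5, 100, 0.5, 100)
        assert out["z"] == pytest.approx(0.0)
        out2 = val.compare_correlations(0.8, 200, 0.1, 200)
        assert out2["p_value"] < 0.001

    def test_dependent_correlation_bootstrap(self, rng):
        y = rng.standard_normal(200)
        good = y + 0.5 * rng.standard_normal(200)
        bad = rng.standard_normal(200)
        out = val.compare_correlations_dependent(good, bad, y, seed=0)
        assert out["difference"] > 0.5
        assert out["p_value"] < 0.01
        same = val.compare_correlations_dependent(good, good, y, seed=0)
        assert same["difference"] == pytest.approx(0.0)


class TestTaskFC:
    @staticmethod
    def make_task_cohort(seed, n_sub=40, coupling=0.0, link=0.0):
        """Task runs where the CS+ window coupling on lAMY-lHIP varies with a
        subject trait that (optionally) drives the learning score."""
        rng = np.random.default_rng(seed)
        design = sg.StudyDesign("S2", "FL", "SCR", n_sub)
        events, _ = sg.gen_task_events(design, n_trials_per_condition=15,
                                       seed=seed, n_subjects=0)
        timeseries = {}
        trait = rng.standard_normal(n_sub)
        for s in range(n_sub):
            r_plus = np.clip(coupling + 0.25 * trait[s] * (coupling > 0), -0.9, 0.9)
            _, ts = sg.gen_task_events(
                design, n_trials_per_condition=15,
                coupling_plus={"lAMY-lHIP": float(r_plus)}, coupling_minus={},
                seed=int(rng.integers(2**31)), n_subjects=1, schedule=events,
            )
            timeseries[s] = ts[0]
        scores = pd.DataFrame({
            "subject_id": range(n_sub),
            "z_score": link * trait + np.sqrt(max(0.0, 1 - link**2))
            * rng.standard_normal(n_sub),
        })
        cov = pd.DataFrame({
            "subject_id": range(n_sub),
            "age": rng.uniform(20, 30, n_sub),
            "sex": rng.integers(0, 2, n_sub),
        })
        return timeseries, events, scores, cov

    def test_null_type_i_approximately_alpha(self):
        from connlearn.network import default_edge_set

        rejections = 0
        n_runs = 30
        for i in range(n_runs):
            ts, ev, scores, cov = self.make_task_cohort(seed=i, coupling=0.0)
            res = cl.taskfc_regression_test(
                ts, ev, ["lAMY-lHIP", "lHIP-lPFC"], scores, cov, 2.0,
                default_edge_set(), n_random_sets=2, seed=i,
            )
            rejections += res.p_value < 0.05
        assert rejections <= 5  # binomial(30, .05) upper tail

    def test_planted_link_beats_random_sets(self):
        from connlearn.network import default_edge_set

        wins = 0
        n_runs = 8
        for i in range(n_runs):
            ts, ev, scores, cov = self.make_task_cohort(
                seed=100 + i, n_sub=60, coupling=0.5, link=0.8
            )
            res = cl.taskfc_regression_test(
                ts, ev, ["lAMY-lHIP"], scores, cov, 2.0, default_edge_set(),
                n_random_sets=20, seed=i,
            )
            wins += res.r_squared > res.max_random_r2
        assert wins >= 5

    def test_too_few_trials_rejected(self):
        from connlearn.network import default_edge_set

        ts, ev, scores, cov = self.make_task_cohort(seed=0, n_sub=5)
        short = ev.iloc[:6]
        with pytest.raises(ValueError, match="trials per condition"):
            cl.taskfc_regression_test(ts, short, ["lAMY-lHIP"], scores, cov, 2.0,
                                      default_edge_set(), seed=0)


class TestMvnSimulation:
    def test_null_reference_r2_near_expectation(self, rng):
        d = random_design(rng, n=2000, p=10)
        res = cl.mvn_simulation_comparison(d, selected=["x0", "x1", "x2"], D=200,
                                           n_per_dataset=40, seed=0)
        # 3 regressors, no covariate columns in this design: E[R^2] = p/(n-1)
        expected = 3 / 39
        assert abs(res.r2_selected.mean() - expected) < 0.03
        assert abs(res.r2_random.mean() - expected) < 0.03
        assert res.p_value > 0.01  # no systematic difference

    def test_planted_effect_selected_beats_random(self, rng):
        hits = 0
        for i in range(20):
            d = random_design(rng, n=300, p=15, r2=0.3)
            res = cl.mvn_simulation_comparison(d, selected=["x0", "x1", "x2"],
                                               D=100, n_per_dataset=40,
                                               seed=rng.integers(2**31))
            hits += (res.p_value < 0.05) and (res.t_statistic > 0)
        assert hits >= 16

    @pytest.mark.parametrize("n_per", [40, 90, 300])
    def test_sample_size_does_not_flip_ordering(self, rng, n_per):
        d = random_design(rng, n=400, p=12, r2=0.3)
        res = cl.mvn_simulation_comparison(d, selected=["x0", "x1", "x2"], D=60,
                                           n_per_dataset=n_per, seed=1)
        assert res.r2_selected.mean() > res.r2_random.mean()

    def test_bootstrap_modes(self, rng):
        d = random_design(rng, n=200, p=8, r2=0.3)
        for mode in ("with_replacement", "without_replacement"):
            res = cl.mvn_simulation_comparison(d, selected=["x0", "x1"], D=30,
                                               n_per_dataset=40, seed=2,
                                               bootstrap_mode=mode)
            assert res.r2_selected.mean() > res.r2_random.mean()
        with pytest.raises(ValueError):
            cl.mvn_simulation_comparison(d, selected=["x0"], D=5,
                                         n_per_dataset=400, seed=0,
                                         bootstrap_mode="without_replacement")

    def test_mvn_covariance_converges_to_target(self, rng):
        d = random_design(rng, n=500, p=6, r2=0.2)
        data = np.column_stack([d.y, d.X])
        cov = np.cov(data, rowvar=False)
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        draws = rng.standard_normal((100_000, data.shape[1])) @ L.T
        emp = np.cov(draws, rowvar=False)
        assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.02

    def test_insufficient_alternative_edges(self, rng):
        d = random_design(rng, n=100, p=4)
        with pytest.raises(ValueError, match="fewer non-selected"):
            cl.mvn_simulation_comparison(d, selected=["x0", "x1", "x2"], D=5,
                                         n_per_dataset=40, seed=0)


class TestCronbach:
    def test_identical_items_alpha_one(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, x, x])
        assert cl.cronbach_alpha(X) == pytest.approx(1.0)

    def test_uncorrelated_items_alpha_near_zero(self, rng):
        X = rng.standard_normal((100_000, 5))
        assert abs(cl.cronbach_alpha(X)) < 0.02

    def test_spearman_brown_closed_form(self, rng):
        k, rbar = 9, 0.5
        C = np.full((k, k), rbar)
        np.fill_diagonal(C, 1.0)
        X = rng.multivariate_normal(np.zeros(k), C, size=200_000)
        assert cl.cronbach_alpha(X) == pytest.approx(
            k * rbar / (1 + (k - 1) * rbar), abs=0.01
        )

    def test_agrees_with_pingouin(self, rng):
        import pingouin as pg

        X = rng.standard_normal((50, 6)) + rng.standard_normal((50, 1))
        ours = cl.cronbach_alpha(X)
        ref = pg.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cl.cronbach_alpha(np.ones((5, 3)))
        with pytest.raises(ValueError):
            cl.cronbach_alpha(np.ones((1, 3)))
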