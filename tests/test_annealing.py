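"""OLS fitting, the multi-objective score, and the annealing search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cheekclock as cc
from cheekclock.annealing import metropolis_accept


class TestFitWeights:
    def test_exact_single_predictor(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        cm = pd.DataFrame([ages], index=["c1"],
                          columns=[f"s{i}" for i in range(4)])
        w, b = cc.fit_weights(cm, ages)
        assert w[0] == pytest.approx(1.0, abs=1e-10)
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_exact_two_predictor_system(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=10), rng.normal(size=10)
        ages = 2.0 * x1 - 3.0 * x2 + 5.0
        cm = pd.DataFrame([x1, x2], index=["c1", "c2"],
                          columns=[f"s{i}" for i in range(10)])
        w, b = cc.fit_weights(cm, ages)
        assert np.allclose(w, [2.0, -3.0], atol=1e-10)
        assert b == pytest.approx(5.0, abs=1e-10)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 5))
        ages = rng.normal(60, 10, size=50)
        cm = pd.DataFrame(X.T, index=[f"c{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(50)])
        w, b = cc.fit_weights(cm, ages)
        resid = ages - (b + X @ w)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_rank_deficiency_warns(self):
        x = np.arange(10.0)
        cm = pd.DataFrame([x, 2 * x], index=["c1", "c2"],
                          columns=[f"s{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="rank"):
            cc.fit_weights(cm, x)

    def test_too_few_samples_error(self):
        cm = pd.DataFrame(np.eye(3), index=["a", "b", "c"],
                          columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="samples"):
            cc.fit_weights(cm, np.arange(3.0))


def _survey_from_factors(factors: pd.DataFrame, ages=None):
    idx = factors.index
    if ages is None:
        ages = pd.Series(np.linspace(20, 80, len(idx)), index=idx)
    return cc.SurveyTable(age=pd.Series(ages, index=idx), lifestyle=factors)


class TestDeltaAgePvalues:
    def test_perfect_correlation_floored_not_zero(self):
        idx = [f"s{i}" for i in range(10)]
        f = pd.DataFrame({"smoking": np.linspace(0, 1, 10)}, index=idx)
        p = cc.delta_age_pvalues(np.linspace(0, 1, 10), _survey_from_factors(f))
        assert 0 < p["smoking"] <= 1e-18

    def test_closed_form_small_sample(self):
        # n=5 worked example: p must match the t transform of Pearson r
        delta = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        resp = np.array([0.1, 0.4, 0.35, 0.8, 0.6])
        idx = [f"s{i}" for i in range(5)]
        f = pd.DataFrame({"smoking": resp}, index=idx)
        p = cc.delta_age_pvalues(delta, _survey_from_factors(f))["smoking"]
        r = np.corrcoef(delta, resp)[0, 1]
        t = r * np.sqrt(3 / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), df=3)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_factor_gives_one_with_warning(self):
        idx = [f"s{i}" for i in range(8)]
        f = pd.DataFrame({"smoking": np.full(8, 0.5)}, index=idx)
        with pytest.warns(UserWarning, match="zero-variance"):
            p = cc.delta_age_pvalues(np.arange(8.0), _survey_from_factors(f))
        assert p["smoking"] == 1.0

    def test_null_pvalues_uniform(self):
        # independent factor: p should be U(0,1) across simulations
        rng = np.random.default_rng(42)
        idx = [f"s{i}" for i in range(50)]
        ps = []
        for _ in range(1000):
            f = pd.DataFrame({"smoking": rng.random(50)}, index=idx)
            d = rng.normal(size=50)
            ps.append(cc.delta_age_pvalues(d, _survey_from_factors(f))["smoking"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_age_adjustment_removes_age_component(self):
        # delta == -age: unadjusted tests flag an age-correlated factor,
        # the partial test does not
        rng = np.random.default_rng(3)
        n = 200
        ages = rng.uniform(20, 90, n)
        z = (ages - ages.mean()) / ages.std()
        resp = stats.norm.cdf(0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(n))
        idx = [f"s{i}" for i in range(n)]
        f = pd.DataFrame({"smoking": resp}, index=idx)
        survey = _survey_from_factors(f, ages=ages)
        delta = -ages + rng.normal(0, 0.5, n)
        plain = cc.delta_age_pvalues(delta, survey)["smoking"]
        partial = cc.delta_age_pvalues(delta, survey, ages=ages)["smoking"]
        assert plain < 1e-10 and partial > 0.01


class TestScoreModel:
    def test_total_is_weighted_sum_of_components(self, small_cluster_matrix,
                                                 small_cohort):
        survey = small_cohort["survey"]
        cm = small_cluster_matrix
        ages = survey.age.loc[cm.sample_ids]
        cfg = cc.AnnealConfig(w_rmse=1.0, w_sig=1.0, w_cplx=0.1)
        model = cc.anneal(cm, ages, survey, cfg, seed=0)
        comp = model.score_components
        expected = (cfg.w_rmse * comp["rmse_term"]
                    + cfg.w_sig * comp["lifestyle_term"]
                    + cfg.w_cplx * comp["complexity_term"])
        assert model.total_score == pytest.approx(expected, rel=1e-12)
        rescored = cc.score_model(model, cm, ages, survey, cfg)
        assert rescored.total_score == pytest.approx(model.total_score, rel=1e-9)

    def test_zero_sig_weight_reduces_to_accuracy_plus_complexity(
            self, small_cluster_matrix, small_cohort):
        survey = small_cohort["survey"]
        cm = small_cluster_matrix
        ages = survey.age.loc[cm.sample_ids]
        cfg = cc.AnnealConfig(w_sig=0.0)
        model = cc.anneal(cm, ages, survey, cfg, seed=1)
        comp = model.score_components
        assert model.total_score == pytest.approx(
            comp["rmse_term"] + cfg.w_cplx * comp["complexity_term"], rel=1e-12)

    def test_empty_model_rejected(self, small_cluster_matrix, small_cohort):
        empty = cc.ClockModel([], np.array([]), 0.0, {}, 0.0)
        with pytest.raises(ValueError, match="empty"):
            cc.score_model(empty, small_cluster_matrix,
                           small_cohort["survey"].age, small_cohort["survey"])


class TestAnneal:
    def test_same_seed_same_model(self, small_cluster_matrix, small_cohort):
        survey = small_cohort["survey"]
        ages = survey.age.loc[small_cluster_matrix.sample_ids]
        cfg = cc.AnnealConfig(iterations=300)
        a = cc.anneal(small_cluster_matrix, ages, survey, cfg, seed=5)
        b = cc.anneal(small_cluster_matrix, ages, survey, cfg, seed=5)
        assert a.cluster_ids == b.cluster_ids
        assert np.array_equal(a.weights, b.weights)
        assert a.total_score == b.total_score

    def test_best_score_trace_non_increasing(self, small_cluster_matrix,
                                             small_cohort):
        survey = small_cohort["survey"]
        ages = survey.age.loc[small_cluster_matrix.sample_ids]
        _, trace = cc.anneal(small_cluster_matrix, ages, survey,
                             cc.AnnealConfig(iterations=400), seed=2,
                             return_trace=True)
        best = trace["best_score"].to_numpy()
        assert (np.diff(best) <= 1e-12).all()

    def test_zero_temperature_limit_is_greedy(self, small_cluster_matrix,
                                              small_cohort):
        survey = small_cohort["survey"]
        ages = survey.age.loc[small_cluster_matrix.sample_ids]
        cfg = cc.AnnealConfig(iterations=400, t0=1e-12, t_min=1e-15)
        _, trace = cc.anneal(small_cluster_matrix, ages, survey, cfg,
                             seed=3, return_trace=True)
        current = trace["current_score"].to_numpy()
        assert (np.diff(current) <= 1e-9).all()

    def test_finds_enumerated_optimum_on_small_universe(self, small_cohort):
        """One seeded repeat of the annealer-vs-exhaustive-search check."""
        c = small_cohort
        cmap12 = c["cmap"].subset(c["cmap"].cluster_ids[:12])
        cm = cc.average_clusters(c["matrix"], cmap12)
        survey = c["survey"]
        ages = survey.age.loc[cm.sample_ids]
        cfg = cc.AnnealConfig(iterations=5000, max_model_size=3)
        best = np.inf
        for size in (1, 2, 3):
            for subset in itertools.combinations(cm.cluster_ids, size):
                w, b = cc.fit_weights(cm.values.loc[list(subset)], ages)
                model = cc.ClockModel(list(subset), w, b, {}, 0.0)
                scored = cc.score_model(model, cm, ages, survey, cfg)
                best = min(best, scored.total_score)
        annealed = cc.anneal(cm, ages, survey, cfg, seed=0)
        assert annealed.total_score == pytest.approx(best, abs=1e-9)

    def test_too_few_clusters_rejected(self, small_cohort):
        survey = small_cohort["survey"]
        cm = cc.average_clusters(small_cohort["matrix"],
                                 small_cohort["cmap"].subset(
                                     small_cohort["cmap"].cluster_ids[:1]))
        with pytest.raises(ValueError, match="2 clusters"):
            cc.anneal(cm, survey.age, survey, seed=0)


class TestMetropolisRule:
    def test_improving_moves_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-d, 0.5, rng)
                   for d in (0.0, 1e-9, 1.0, 100.0))

    def test_worsening_acceptance_matches_boltzmann(self):
        rng = np.random.default_rng(7)
        T, dS, n = 2.0, 1.5, 20_000
        accepted = sum(metropolis_accept(dS, T, rng) for _ in range(n))
        expected = np.exp(-dS / T)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(accepted / n - expected) < 3 * se


class TestTrainMany:
    def test_fixed_seeds_are_stable_and_spread_positive(
            self, small_cluster_matrix, small_cohort):
        survey = small_cohort["survey"]
        ages = survey.age.loc[small_cluster_matrix.sample_ids]
        cfg = cc.AnnealConfig(iterations=200)
        models = cc.train_many(small_cluster_matrix, ages, survey, cfg,
                               n_models=8, base_seed=100)
        again = cc.train_many(small_cluster_matrix, ages, survey, cfg,
                              n_models=8, base_seed=100)
        assert [m.total_score for m in models] == [m.total_score for m in again]
        assert np.var([m.total_score for m in models]) > 0

    def test_invalid_count(self, small_cluster_matrix, small_cohort):
        with pytest.raises(ValueError):
            cc.train_many(small_cluster_matrix, small_cohort["survey"].age,
                          small_cohort["survey"], n_models=0)
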