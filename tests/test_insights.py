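"""Trajectory binning, factor overlaps, context enrichment, variability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cheekclock as cc
from cheekclock.insights import split_by_delta


def _m_matrix(values, probe_ids=None):
    probe_ids = probe_ids or [f"cg{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=probe_ids,
                      columns=[f"s{j}" for j in range(len(values[0]))])
    return cc.MethylationMatrix(df, "m")


class TestBinnedProfile:
    def test_linear_cpg_mean_trajectory(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 90, 200)
        mat = _m_matrix([0.1 * ages, np.full(200, 2.0)])
        profile = cc.binned_profile(mat, ages, n_bins=15, statistic="mean")
        assert profile.correlation["cg0"] > 0.99
        # bin means of a linear CpG equal 0.1 * (bin mean age)
        assert np.isnan(profile.correlation["cg1"])  # constant: r undefined
        assert (profile.values.loc["cg1"] == 2.0).all()

    @pytest.mark.parametrize("n_bins", [2, 5, 15])
    def test_trend_correlation_across_bin_counts(self, n_bins):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 90, 300)
        mat = _m_matrix([-0.05 * ages])
        profile = cc.binned_profile(mat, ages, n_bins=n_bins)
        assert profile.correlation["cg0"] < -0.99

    def test_variance_mode(self):
        rng = np.random.default_rng(2)
        ages = np.sort(rng.uniform(20, 90, 400))
        # noise grows with age: variance trajectory rises
        vals = rng.normal(0, 0.1 + 0.01 * (ages - 20), size=(1, 400))
        profile = cc.binned_profile(_m_matrix(vals), ages, n_bins=10,
                                    statistic="variance")
        assert profile.correlation["cg0"] > 0.8

    def test_empty_bin_suggests_fewer_bins(self):
        ages = np.concatenate([np.full(10, 25.0), np.full(10, 85.0)])
        mat = _m_matrix([np.linspace(0, 1, 20)])
        with pytest.raises(ValueError, match="fewer bins"):
            cc.binned_profile(mat, ages, n_bins=15)

    def test_default_bin_count_is_15(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(18, 93, 500)
        profile = cc.binned_profile(_m_matrix([0.1 * ages]), ages)
        assert profile.values.shape[1] == 15


class TestSelectByCorrelation:
    def test_planted_monotone_cpgs_land_in_high_window(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 90, 300)
        vals = np.vstack([0.05 * ages + rng.normal(0, 0.05, 300),
                          rng.normal(0, 1, (5, 300))])
        profile = cc.binned_profile(_m_matrix(vals), ages, n_bins=10)
        sets = cc.select_by_correlation(profile)
        assert "cg0" in sets[(0.95, 1.0)]

    def test_full_window_selects_all_defined(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(20, 90, 100)
        vals = np.vstack([rng.normal(0, 1, (3, 100)), np.full((1, 100), 1.0)])
        profile = cc.binned_profile(_m_matrix(vals), ages, n_bins=5)
        sets = cc.select_by_correlation(profile, windows=[(0.0, 1.0)])
        assert len(sets[(0.0, 1.0)]) == 3  # constant probe has undefined r

    def test_empty_selection_is_not_an_error(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(20, 90, 100)
        profile = cc.binned_profile(_m_matrix(rng.normal(size=(4, 100))),
                                    ages, n_bins=5)
        sets = cc.select_by_correlation(profile, windows=[(0.9999, 1.0)])
        assert len(sets[(0.9999, 1.0)]) == 0


class TestFactorCorrelationOverlap:
    def test_identical_factors_full_overlap_and_symmetry(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(50, 30)),
                            index=[f"f{i}" for i in range(50)],
                            columns=[f"s{j}" for j in range(30)])
        f = rng.random(30)
        factors = pd.DataFrame({"a": f, "b": f, "c": rng.random(30)},
                               index=vals.columns)
        sets, overlap = cc.factor_correlation_overlap(vals, factors, top_n=10)
        assert overlap.loc["a", "b"] == 10
        assert overlap.equals(overlap.T)
        assert list(sets["a"]) == list(sets["b"])

    def test_independent_factors_overlap_near_chance(self):
        rng = np.random.default_rng(8)
        n_feat, top_n = 2000, 100
        vals = pd.DataFrame(rng.normal(size=(n_feat, 60)),
                            index=[f"f{i}" for i in range(n_feat)],
                            columns=[f"s{j}" for j in range(60)])
        factors = pd.DataFrame(rng.random((60, 2)), index=vals.columns,
                               columns=["a", "b"])
        _, overlap = cc.factor_correlation_overlap(vals, factors, top_n=top_n)
        expected = top_n**2 / n_feat  # hypergeometric expectation = 5
        assert overlap.loc["a", "b"] <= expected + 12

    def test_top_n_capped_with_warning(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(5, 20)),
                            index=[f"f{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(20)])
        factors = pd.DataFrame({"a": rng.random(20)}, index=vals.columns)
        with pytest.warns(UserWarning, match="capped"):
            sets, _ = cc.factor_correlation_overlap(vals, factors, top_n=100)
        assert len(sets["a"]) == 5


def _manifest(relations, probe_ids):
    return cc.ProbeManifest(pd.DataFrame({
        "chrom": ["1"] * len(probe_ids),
        "pos": np.arange(1, len(probe_ids) + 1),
        "island_relation": relations,
        "genes": [[] for _ in probe_ids],
    }, index=pd.Index(probe_ids, name="probe_id")))


class TestContextEnrichment:
    def test_stated_table_odds_ratio_and_exact_p(self):
        # 10/20 of the set in islands vs 100/400 of the rest: OR = 3
        probes = [f"p{i}" for i in range(420)]
        rel = (["Island"] * 10 + ["OpenSea"] * 10          # the set
               + ["Island"] * 100 + ["OpenSea"] * 300)     # the rest
        man = _manifest(rel, probes)
        res = cc.context_enrichment(probes[:20], probes, man)
        assert res.loc["Island", "odds_ratio"] == pytest.approx(3.0)
        # independent exact oracle: two-sided Fisher p by summing
        # hypergeometric point masses <= that of the observed table
        dist = stats.hypergeom(420, 110, 20)
        obs = dist.pmf(10)
        expected = sum(dist.pmf(k) for k in range(21) if dist.pmf(k) <= obs * (1 + 1e-9))
        assert res.loc["Island", "p"] == pytest.approx(expected, rel=1e-6)

    def test_set_equals_background_is_null(self):
        probes = [f"p{i}" for i in range(40)]
        rel = ["Island"] * 10 + ["Shore"] * 10 + ["Shelf"] * 10 + ["OpenSea"] * 10
        res = cc.context_enrichment(probes, probes, _manifest(rel, probes))
        assert (res["odds_ratio"] == 1.0).all()
        assert (res["p"] == 1.0).all()

    def test_empty_category_reported_missing(self):
        probes = [f"p{i}" for i in range(20)]
        rel = ["Island"] * 10 + ["OpenSea"] * 10  # no Shore/Shelf anywhere
        res = cc.context_enrichment(probes[:5], probes, _manifest(rel, probes))
        assert np.isnan(res.loc["Shore", "odds_ratio"])

    def test_set_must_be_subset(self):
        probes = [f"p{i}" for i in range(10)]
        man = _manifest(["Island"] * 10, probes)
        with pytest.raises(ValueError, match="subset"):
            cc.context_enrichment(["other"], probes, man)


class TestDifferentialVariability:
    def test_planted_variance_inflation_detected(self):
        rng = np.random.default_rng(10)
        n_cpg, n_lo, n_hi = 2000, 40, 40
        lo = rng.normal(0, 1, size=(n_cpg, n_lo))
        hi = rng.normal(0, 1, size=(n_cpg, n_hi))
        hi[:100] *= np.sqrt(3.0)  # 3x variance inflation in the first 100
        mat = _m_matrix(np.hstack([lo, hi]))
        low_ids = list(mat.sample_ids[:n_lo])
        high_ids = list(mat.sample_ids[n_lo:])
        res = cc.differential_variability(mat, low_ids, high_ids)
        hits = set(res.index[res["more_variable_high"]])
        planted = {f"cg{i}" for i in range(100)}
        assert len(hits & planted) > 50
        assert len(hits - planted) < len(hits & planted) * 0.2

    def test_zero_variance_everywhere_reported_missing(self):
        vals = np.vstack([np.ones(12), np.random.default_rng(1).normal(size=12)])
        mat = _m_matrix(vals)
        res = cc.differential_variability(mat, list(mat.sample_ids[:6]),
                                          list(mat.sample_ids[6:]))
        assert np.isnan(res.loc["cg0", "p"])

    def test_group_size_minimum(self):
        mat = _m_matrix(np.random.default_rng(2).normal(size=(3, 10)))
        with pytest.raises(ValueError, match="at least 3"):
            cc.differential_variability(mat, list(mat.sample_ids[:2]),
                                        list(mat.sample_ids[2:]))

    def test_split_by_delta_default_thresholds(self):
        delta = pd.Series([-7.0, -2.0, 0.0, 4.0, 6.0, 9.0],
                          index=list("abcdef"))
        low, high = split_by_delta(delta)
        assert low == ["a"] and high == ["e", "f"]
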