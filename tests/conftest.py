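"""Shared fixtures: small seeded synthetic cohorts used across the suite."""

import pytest

import cheekclock as cc


def _prepare(matrix, manifest, cmap):
    """Filter the matrix and average whole surviving clusters."""
    filtered, report = cc.filter_probes(matrix, manifest)
    surviving = set(filtered.probe_ids)
    keep = [c for c in cmap.cluster_ids
            if set(cmap.members(c)) <= surviving]
    cm = cc.average_clusters(filtered, cmap.subset(keep))
    return filtered, report, cm


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples, 40 clusters (5 age + 2 lifestyle planted), seed 7."""
    cfg = cc.CohortConfig(
        n_samples=120, n_true_clusters=40, n_age_clusters=5,
        n_lifestyle_clusters=2,
    )
    matrix, survey, manifest, cmap, truth = cc.generate_cohort(cfg, seed=7)
    return {
        "config": cfg, "matrix": matrix, "survey": survey,
        "manifest": manifest, "cmap": cmap, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_cluster_matrix(small_cohort):
    _, _, cm = _prepare(small_cohort["matrix"], small_cohort["manifest"],
                        small_cohort["cmap"])
    return cm


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Exactly deterministic planted structure: no noise of any kind."""
    cfg = cc.CohortConfig(
        n_samples=60, n_true_clusters=20, n_age_clusters=4,
        n_lifestyle_clusters=0, noise_sd=0.0, cell_delta_sd=0.0,
        cluster_profile_sd=0.0,
    )
    matrix, survey, manifest, cmap, truth = cc.generate_cohort(cfg, seed=3)
    return {
        "config": cfg, "matrix": matrix, "survey": survey,
        "manifest": manifest, "cmap": cmap, "truth": truth,
    }
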