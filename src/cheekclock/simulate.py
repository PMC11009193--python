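"""Seedable synthetic buccal-methylation cohorts with planted structure.

The generator emulates the features of an adult cheek-swab methylation study
that the downstream machinery needs to be exercised against: a wide adult age
range, CpG clusters whose M values drift linearly with age, lifestyle and
health survey responses correlated with age, lifestyle effects written into
dedicated CpG clusters, a two-cell-type mixture background, sex-chromosome
probes carrying an XX/XY signal, and technical replicate pairs.

All randomness flows from one integer seed through a single
``numpy.random.Generator``, so identical seeds yield byte-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    ISLAND_RELATIONS,
    ClusterMap,
    MethylationMatrix,
    ProbeManifest,
    SurveyTable,
)

__all__ = ["CohortConfig", "SyntheticTruth", "generate_cohort", "add_replicates",
           "DEFAULT_FACTOR_AGE_CORR", "LIFESTYLE_FACTORS"]

#: The eleven lifestyle and health survey questions, scaled to [0, 1].
LIFESTYLE_FACTORS = (
    "self_rated_health",
    "self_perceived_aging",
    "sleep_quality",
    "stress_level",
    "social_satisfaction",
    "diet_plant_fraction",
    "exercise",
    "smoking",
    "alcohol",
    "immune_health",
    "bmi",
)

# Default factor-age correlations.  Signs follow the cohort trends the study
# design implies (smoking and reported stress decline with age; self-perceived
# aging rises); magnitudes are modest, as is typical for self-report data.
DEFAULT_FACTOR_AGE_CORR: dict[str, float] = {
    "self_rated_health": -0.10,
    "self_perceived_aging": 0.20,
    "sleep_quality": 0.10,
    "stress_level": -0.30,
    "social_satisfaction": 0.15,
    "diet_plant_fraction": 0.10,
    "exercise": -0.10,
    "smoking": -0.25,
    "alcohol": 0.10,
    "immune_health": -0.10,
    "bmi": 0.10,
}

_ISLAND_PROBS = (0.31, 0.23, 0.10, 0.36)  # Island, Shore, Shelf, OpenSea


@dataclass
class CohortConfig:
    """Generator settings; the defaults define the standard synthetic cohort.

    Attributes
    ----------
    n_samples, n_true_clusters, n_probes
        Cohort and feature dimensions.  ``n_probes`` counts autosomal probes
        and is split over clusters (each cluster gets >= 1 probe); ``None``
        means four probes per cluster on average.
    n_age_clusters, n_lifestyle_clusters
        How many clusters carry a planted age slope, and how many additionally
        carry a lifestyle effect.  The two sets are disjoint cluster-id sets,
        but lifestyle clusters also carry their own age slope when
        ``lifestyle_clusters_age_linked`` is true (flagged in the truth
        record): a lifestyle signal can only surface in delta age if it rides
        on inputs that predict age at all.
    age_slope_mean, age_slope_sd
        Planted slopes are ``sign * |N(mean, sd)|`` in M units per year, sign
        drawn fairly — both hyper- and hypomethylation drift occur.
    lifestyle_effect_factors, lifestyle_effect_size
        Which factors get planted effects (round-robin over the lifestyle
        clusters) and the effect size in M units per unit response.
    noise_sd, cluster_profile_sd
        Residual probe-level M noise, and the s.d. of the per-cluster shared
        latent component (the correlated variation that defines a cluster;
        unlike probe noise it does not average out within a cluster).
    cell_alpha, cell_probe_fraction, cell_delta_sd
        Two pseudo cell types mixed per sample with Dirichlet(``cell_alpha``)
        proportions; a ``cell_probe_fraction`` subset of probes differs
        between the types by ``N(0, cell_delta_sd)`` M units.
    """

    n_samples: int = 500
    n_true_clusters: int = 300
    n_probes: int | None = None
    n_age_clusters: int = 20
    n_lifestyle_clusters: int = 5
    age_range: tuple[float, float] = (18.0, 93.0)
    age_slope_mean: float = 0.02
    age_slope_sd: float = 0.005
    factor_age_corr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_AGE_CORR)
    )
    lifestyle_effect_factors: tuple[str, ...] = ("smoking",)
    lifestyle_effect_size: float = 0.5
    lifestyle_clusters_age_linked: bool = True
    lifestyle_age_slope_scale: float = 1.0
    noise_sd: float = 0.3
    cluster_profile_sd: float = 0.1
    cell_alpha: tuple[float, ...] = (8.0, 4.0)
    cell_probe_fraction: float = 0.1
    cell_delta_sd: float = 0.5
    n_x_probes: int = 8
    n_y_probes: int = 8
    replicate_tech_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_age_clusters + self.n_lifestyle_clusters > self.n_true_clusters:
            raise ValueError(
                "planted clusters (age + lifestyle) exceed n_true_clusters"
            )
        if self.n_probes is None:
            self.n_probes = 4 * self.n_true_clusters
        if self.n_probes < self.n_true_clusters:
            raise ValueError("n_probes must be >= n_true_clusters")
        if self.noise_sd < 0 or self.replicate_tech_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        unknown = set(self.factor_age_corr) - set(LIFESTYLE_FACTORS)
        if unknown:
            raise ValueError(f"unknown lifestyle factors: {sorted(unknown)}")
        unknown = set(self.lifestyle_effect_factors) - set(LIFESTYLE_FACTORS)
        if unknown:
            raise ValueError(f"unknown effect factors: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery checks."""

    planted_age_clusters: dict[str, float]           # cluster id -> M/yr slope
    planted_lifestyle_effects: dict[str, dict[str, float]]  # factor -> {cid: effect}
    lifestyle_clusters_age_linked: bool              # overlap flag: lifestyle
    #   clusters also appear in planted_age_clusters when True
    noise_sd: float
    replicate_tech_sd: float
    cell_profiles: pd.DataFrame                      # reference probes x types (M)
    cell_proportions: pd.DataFrame                   # samples x types
    seed: int


def _correlated_uniform(z_age: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """A [0,1]-valued response whose latent Gaussian has correlation rho with age."""
    eps = rng.standard_normal(z_age.shape[0])
    latent = rho * z_age + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return norm.cdf(latent)


def generate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Generate one synthetic cohort.

    Returns
    -------
    (matrix, survey, manifest, cluster_map, truth)
        ``matrix`` is an M-scale :class:`MethylationMatrix`; ``cluster_map``
        is the ground-truth partition of autosomal probes; ``truth`` records
        everything that was planted.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n, n_clusters = cfg.n_samples, cfg.n_true_clusters

    sample_ids = [f"s{i:04d}" for i in range(n)]
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    z_age = (ages - ages.mean()) / ages.std()

    # --- survey -----------------------------------------------------------
    lifestyle = pd.DataFrame(
        {
            f: _correlated_uniform(z_age, cfg.factor_age_corr.get(f, 0.0), rng)
            for f in LIFESTYLE_FACTORS
        },
        index=sample_ids,
    )
    sex = rng.choice([-1.0, 1.0], size=n)  # +1 = XX-like, -1 = XY-like
    demographics = pd.DataFrame({"gender": sex}, index=sample_ids)
    categorical = pd.DataFrame(
        {
            "race_ethnicity": rng.choice(["groupA", "groupB", "groupC", "groupD"], size=n),
            "education": rng.choice(["secondary", "college", "postgrad"], size=n),
        },
        index=sample_ids,
    )
    technical = pd.DataFrame(
        {
            "plate": rng.choice([f"P{i}" for i in range(1, 6)], size=n),
            "array_position": rng.integers(1, 9, size=n),
        },
        index=sample_ids,
    )

    # --- cluster layout: every autosomal probe belongs to one cluster -----
    extra = rng.multinomial(cfg.n_probes - n_clusters, np.full(n_clusters, 1.0 / n_clusters))
    sizes = 1 + extra
    cluster_ids = [f"cl{i:04d}" for i in range(n_clusters)]
    probe_ids: list[str] = []
    assignment: dict[str, list[str]] = {}
    p = 0
    for cid, size in zip(cluster_ids, sizes):
        members = [f"cg{p + j:06d}" for j in range(size)]
        assignment[cid] = members
        probe_ids.extend(members)
        p += size
    cluster_map = ClusterMap(assignment)

    # planted structure: disjoint id sets, lifestyle clusters may still carry
    # their own age slope (recorded via the overlap flag)
    planted = rng.choice(n_clusters, cfg.n_age_clusters + cfg.n_lifestyle_clusters, replace=False)
    age_cids = [cluster_ids[i] for i in planted[: cfg.n_age_clusters]]
    ls_cids = [cluster_ids[i] for i in planted[cfg.n_age_clusters:]]

    def _slope() -> float:
        return rng.choice([-1.0, 1.0]) * abs(rng.normal(cfg.age_slope_mean, cfg.age_slope_sd))

    age_slopes = {cid: _slope() for cid in age_cids}
    if cfg.lifestyle_clusters_age_linked:
        # lifestyle-responsive clusters may be weaker age markers than the
        # cleanest age clusters; scale < 1 puts them in that regime
        age_slopes.update(
            {cid: cfg.lifestyle_age_slope_scale * _slope() for cid in ls_cids}
        )

    # effects point along each cluster's age-drift direction: a higher
    # response pushes the methylome toward its older state, so the planted
    # factor raises delta age coherently across clusters
    ls_effects: dict[str, dict[str, float]] = {f: {} for f in cfg.lifestyle_effect_factors}
    if cfg.lifestyle_effect_factors:
        for j, cid in enumerate(ls_cids):
            f = cfg.lifestyle_effect_factors[j % len(cfg.lifestyle_effect_factors)]
            direction = float(np.sign(age_slopes[cid])) if cid in age_slopes else 1.0
            ls_effects[f][cid] = cfg.lifestyle_effect_size * direction

    # --- autosomal M values ----------------------------------------------
    # bimodal probe baselines, as methylation arrays show
    lo = rng.normal(-2.5, 1.0, size=cfg.n_probes)
    hi = rng.normal(2.5, 1.0, size=cfg.n_probes)
    baseline = np.where(rng.random(cfg.n_probes) < 0.5, lo, hi)

    # two pseudo cell types: type B differs on a probe subset
    n_ref = max(2, int(round(cfg.cell_probe_fraction * cfg.n_probes)))
    ref_idx = rng.choice(cfg.n_probes, n_ref, replace=False)
    delta = np.zeros(cfg.n_probes)
    delta[ref_idx] = rng.normal(0.0, cfg.cell_delta_sd, size=n_ref)
    props = rng.dirichlet(cfg.cell_alpha, size=n)  # samples x 2

    age_mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    row_of = {pid: i for i, pid in enumerate(probe_ids)}
    values = baseline[:, None] + np.outer(delta, props[:, 1])
    # what makes a cluster a cluster: a shared per-sample latent component,
    # the correlated biological variation member probes have in common
    if cfg.cluster_profile_sd > 0:
        profiles = rng.normal(0.0, cfg.cluster_profile_sd, size=(n_clusters, n))
        for ci, cid in enumerate(cluster_ids):
            rows = [row_of[m] for m in assignment[cid]]
            values[rows, :] += profiles[ci][None, :]
    for cid, slope in age_slopes.items():
        rows = [row_of[m] for m in assignment[cid]]
        values[rows, :] += slope * (ages - age_mid)[None, :]
    for f, effects in ls_effects.items():
        resp = lifestyle[f].to_numpy() - 0.5
        for cid, eff in effects.items():
            rows = [row_of[m] for m in assignment[cid]]
            values[rows, :] += eff * resp[None, :]
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, size=values.shape)

    # --- sex chromosome probes -------------------------------------------
    x_ids = [f"cgX{j:04d}" for j in range(cfg.n_x_probes)]
    y_ids = [f"cgY{j:04d}" for j in range(cfg.n_y_probes)]
    sex_noise = max(cfg.noise_sd, 0.2)
    # XX-like: X hemimethylated (M near 0), Y without signal (very low M);
    # XY-like: X shifted off 0, Y probes carry signal
    x_center = np.where(sex == 1.0, 0.0, 2.0)
    y_center = np.where(sex == 1.0, -4.0, 1.0)
    x_vals = x_center[None, :] + rng.normal(0.0, sex_noise, size=(cfg.n_x_probes, n))
    y_vals = y_center[None, :] + rng.normal(0.0, sex_noise, size=(cfg.n_y_probes, n))

    all_ids = probe_ids + x_ids + y_ids
    grid = np.vstack([values, x_vals, y_vals])
    matrix = MethylationMatrix(
        pd.DataFrame(grid, index=all_ids, columns=sample_ids), scale="m"
    )

    # --- manifest ---------------------------------------------------------
    chroms = [str(c) for c in rng.integers(1, 23, size=cfg.n_probes)] + \
        ["X"] * cfg.n_x_probes + ["Y"] * cfg.n_y_probes
    relations = list(rng.choice(ISLAND_RELATIONS, size=len(all_ids), p=_ISLAND_PROBS))
    genes = [
        [f"GENE{g}"] if rng.random() < 0.6 else []
        for g in rng.integers(0, 400, size=len(all_ids))
    ]
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": chroms,
                "pos": rng.integers(1, 2_000_000_00, size=len(all_ids)),
                "island_relation": relations,
                "genes": genes,
            },
            index=pd.Index(all_ids, name="probe_id"),
        )
    )

    survey = SurveyTable(
        age=pd.Series(ages, index=sample_ids, name="age"),
        lifestyle=lifestyle,
        demographics=demographics,
        categorical=categorical,
        technical=technical,
        replicate_group=None,
    )
    truth = SyntheticTruth(
        planted_age_clusters=age_slopes,
        planted_lifestyle_effects=ls_effects,
        lifestyle_clusters_age_linked=cfg.lifestyle_clusters_age_linked,
        noise_sd=cfg.noise_sd,
        replicate_tech_sd=cfg.replicate_tech_sd,
        cell_profiles=pd.DataFrame(
            {
                "typeA": baseline[ref_idx],
                "typeB": baseline[ref_idx] + delta[ref_idx],
            },
            index=pd.Index([probe_ids[i] for i in ref_idx], name="probe_id"),
        ),
        cell_proportions=pd.DataFrame(props, index=sample_ids, columns=["typeA", "typeB"]),
        seed=seed,
    )
    return matrix, survey, manifest, cluster_map, truth


def add_replicates(
    matrix: MethylationMatrix,
    survey: SurveyTable,
    n_pairs: int = 190,
    tech_sd: float = 0.1,
    seed: int = 0,
):
    """Duplicate ``n_pairs`` samples with added technical noise on M values.

    Each chosen sample gets a twin column (suffix ``_rep``) whose M values are
    the original's plus ``N(0, tech_sd^2)`` noise; both members share a
    ``replicate_group`` id in the returned survey.  Mirrors a paired-swab
    test-retest design.
    """
    if tech_sd < 0:
        raise ValueError("tech_sd must be >= 0")
    if n_pairs > matrix.n_samples:
        raise ValueError("n_pairs exceeds the number of samples")
    rng = np.random.default_rng(seed)
    chosen = list(
        np.asarray(matrix.sample_ids)[rng.choice(matrix.n_samples, n_pairs, replace=False)]
    )

    work = matrix.to_m() if matrix.scale == "beta" else matrix
    rep_vals = work.values[chosen].to_numpy(copy=True)
    rep_vals += rng.normal(0.0, tech_sd, size=rep_vals.shape) if tech_sd > 0 else 0.0
    rep_ids = [f"{s}_rep" for s in chosen]
    aug_values = pd.concat(
        [work.values, pd.DataFrame(rep_vals, index=work.values.index, columns=rep_ids)],
        axis=1,
    )
    aug = MethylationMatrix(aug_values, "m")
    if matrix.scale == "beta":
        aug = aug.to_beta()

    groups = pd.Series(np.nan, index=survey.sample_ids, dtype=object)
    rep_groups = pd.Series(index=rep_ids, dtype=object)
    for k, s in enumerate(chosen):
        gid = f"rep{k:03d}"
        groups.loc[s] = gid
        rep_groups.loc[f"{s}_rep"] = gid

    def _dup(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df
        extra = df.loc[chosen].set_axis(rep_ids, axis=0)
        return pd.concat([df, extra])

    aug_survey = SurveyTable(
        age=pd.concat([survey.age, survey.age.loc[chosen].set_axis(rep_ids)]),
        lifestyle=_dup(survey.lifestyle),
        demographics=_dup(survey.demographics),
        categorical=_dup(survey.categorical),
        technical=_dup(survey.technical),
        replicate_group=pd.concat([groups, rep_groups]),
    )
    return aug, aug_survey
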