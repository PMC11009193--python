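"""Weighted model ensembles, age-bias rotation, and cross-validation.

The final clock is a weighted mean of the best-scoring annealed models
(lower objective score ⇒ strictly higher weight), recalibrated by an affine
"rotation" that maps the training-set prediction-vs-age regression line onto
the identity so systematic age compression is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annealing import AnnealConfig, ClockModel, anneal
from .clustering import ClusterMatrix
from .datatypes import SurveyTable

__all__ = [
    "EnsembleClock",
    "build_ensemble",
    "predict",
    "fit_rotation",
    "apply_rotation",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass
class EnsembleClock:
    """A ranked model set with normalised combination weights.

    ``cluster_means`` stores the training-set mean of every cluster any
    member model uses; prediction imputes missing cluster values from it, so
    a serialized clock is self-contained.  ``rotation`` is the (slope,
    intercept) of the training-set prediction-vs-age fit, applied inversely
    at predict time.
    """

    models: list[ClockModel]
    ensemble_weights: np.ndarray
    rotation: tuple[float, float] | None = None
    cluster_means: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) < 1:
            raise ValueError("ensemble needs at least one model")
        w = np.asarray(self.ensemble_weights, dtype=float)
        if len(w) != len(self.models):
            raise ValueError("one ensemble weight per model required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must be nonnegative and sum to 1")
        if self.rotation is not None and self.rotation[0] == 0:
            raise ValueError("rotation slope must be nonzero")
        self.ensemble_weights = w

    @property
    def required_clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.models:
            for cid in m.cluster_ids:
                seen.setdefault(cid)
        return list(seen)


def build_ensemble(
    models: list[ClockModel],
    top_k: int = 100,
    cluster_matrix: ClusterMatrix | None = None,
    provenance: dict | None = None,
) -> EnsembleClock:
    """Combine the ``top_k`` best-scoring models into a weighted ensemble.

    Models are sorted by total score ascending; the retained model ``i`` gets
    weight proportional to ``S_worst - S_i + eps`` with
    ``eps = 1e-9 * |S_worst|``, normalised to sum to one — a parameter-free
    rule under which a strictly lower score always means a strictly higher
    weight.  Identical scores fall back to uniform weights.  Passing the
    training ``cluster_matrix`` stores per-cluster training means for
    predict-time imputation.
    """
    if top_k <= 0 or top_k > len(models):
        raise ValueError(f"top_k must be in [1, {len(models)}], got {top_k}")
    order = sorted(range(len(models)), key=lambda i: (models[i].total_score, i))
    kept = [models[i] for i in order[:top_k]]
    scores = np.array([m.total_score for m in kept])
    worst = scores[-1]
    eps = 1e-9 * abs(worst)
    raw = worst - scores + eps
    if raw.sum() <= 0:  # all scores identical (and eps could be 0)
        weights = np.full(top_k, 1.0 / top_k)
    else:
        weights = raw / raw.sum()
    means = None
    if cluster_matrix is not None:
        needed = {cid for m in kept for cid in m.cluster_ids}
        means = cluster_matrix.values.mean(axis=1).loc[sorted(needed)]
    return EnsembleClock(
        models=kept,
        ensemble_weights=weights,
        rotation=None,
        cluster_means=means,
        provenance=provenance or {},
    )


def _member_matrix(clock: EnsembleClock, cluster_values: pd.DataFrame) -> pd.DataFrame:
    """Cluster values restricted to what the clock needs, imputed from stored means."""
    needed = clock.required_clusters
    present = cluster_values.index.intersection(needed)
    absent = [c for c in needed if c not in set(present)]
    if absent and (clock.cluster_means is None
                   or not set(absent) <= set(clock.cluster_means.index)):
        raise KeyError(
            f"clusters absent from input and no stored training mean: {absent[:5]}"
        )
    out = cluster_values.reindex(needed)
    if clock.cluster_means is not None:
        fill = clock.cluster_means.reindex(needed)
        out = out.apply(lambda col: col.fillna(fill), axis=0)
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)].tolist()
        raise KeyError(f"missing cluster values and no stored training mean: {bad[:5]}")
    return out


def predict(
    clock: EnsembleClock,
    cluster_matrix: ClusterMatrix | pd.DataFrame,
    ages=None,
) -> pd.DataFrame:
    """Predict with the ensemble.

    Returns a DataFrame indexed by sample id with ``raw_age`` (the weighted
    mean of member-model outputs), ``predicted_age`` (rotation applied when
    the clock carries one), and ``delta_age`` when chronological ``ages`` are
    supplied.
    """
    values = cluster_matrix.values if isinstance(cluster_matrix, ClusterMatrix) \
        else cluster_matrix
    filled = _member_matrix(clock, values)
    raw = np.zeros(filled.shape[1])
    for w, model in zip(clock.ensemble_weights, clock.models):
        raw += w * model.predict(filled).to_numpy()
    out = pd.DataFrame({"raw_age": raw}, index=values.columns)
    out["predicted_age"] = (
        apply_rotation(out["raw_age"], clock.rotation)
        if clock.rotation is not None else out["raw_age"]
    )
    if ages is not None:
        age = pd.Series(np.asarray(ages, dtype=float), index=values.columns)
        out["delta_age"] = out["predicted_age"] - age
    return out


def fit_rotation(raw_predictions, ages) -> tuple[float, float]:
    """Fit the age-bias rotation: least squares of raw prediction on age.

    Returns ``(slope, intercept)`` of ``raw = slope * age + intercept``; the
    inverse map at predict time makes the corrected-vs-age regression have
    slope 1 and intercept 0 on the training set.
    """
    raw = np.asarray(raw_predictions, dtype=float)
    age = np.asarray(ages, dtype=float)
    if len(raw) < 3:
        raise ValueError("rotation fit needs at least 3 samples")
    slope, intercept = np.polyfit(age, raw, deg=1)
    if abs(slope) < 1e-6:
        raise ValueError("degenerate clock: prediction-vs-age slope is ~0")
    return float(slope), float(intercept)


def apply_rotation(raw, rotation: tuple[float, float]):
    """Invert the fitted bias line: ``corrected = (raw - intercept) / slope``."""
    slope, intercept = rotation
    return (raw - intercept) / slope


@dataclass
class CrossValidationResult:
    """Out-of-fold predictions plus the per-fold ensembles."""

    predictions: pd.DataFrame       # sample × {raw_age, predicted_age, delta_age, fold}
    fold_clocks: list[EnsembleClock]
    fold_assignment: pd.Series      # sample -> fold index


def _replicate_aware_folds(survey: SurveyTable, folds: int, rng) -> pd.Series:
    """Assign samples to folds, keeping replicate groups intact."""
    ids = survey.sample_ids
    group = (
        survey.replicate_group.copy()
        if survey.replicate_group is not None
        else pd.Series(np.nan, index=ids, dtype=object)
    )
    group = group.where(group.notna(), other=pd.Series(
        [f"__solo_{s}" for s in ids], index=ids))
    unique_groups = group.unique()
    perm = rng.permutation(len(unique_groups))
    fold_of_group = {unique_groups[j]: int(perm[j] % folds) for j in range(len(unique_groups))}
    return group.map(fold_of_group)


def cross_validate(
    cluster_matrix: ClusterMatrix,
    ages,
    survey: SurveyTable,
    folds: int = 10,
    models_per_fold: int = 12,
    config: AnnealConfig | None = None,
    seed: int = 0,
) -> CrossValidationResult:
    """Tenfold (by default) cross-validation with per-fold annealed ensembles.

    For each fold: ``models_per_fold`` annealing runs on the training split,
    an ensemble over all of them, a rotation fitted on the training split,
    and predictions for the held-out samples.  Samples sharing a replicate
    group are always assigned to the same fold so test-retest twins can never
    leak across the split.  Every sample receives exactly one out-of-fold
    prediction.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cfg = config or AnnealConfig()
    rng = np.random.default_rng(seed)
    age = pd.Series(np.asarray(ages, dtype=float), index=cluster_matrix.sample_ids)
    assignment = _replicate_aware_folds(survey, folds, rng)

    min_needed = cfg.max_model_size + 2
    preds = []
    fold_clocks: list[EnsembleClock] = []
    for f in range(folds):
        test_ids = assignment.index[assignment == f].tolist()
        train_ids = assignment.index[assignment != f].tolist()
        if len(test_ids) == 0:
            raise ValueError(f"fold {f} is empty; reduce the number of folds")
        if len(train_ids) < min_needed:
            raise ValueError(
                f"fold {f} leaves only {len(train_ids)} training samples; "
                f"need at least {min_needed}"
            )
        train_cm = cluster_matrix.subset_samples(train_ids)
        train_survey = survey.subset(train_ids)
        base = (seed * 100003 + f * 1009) % (2**31)
        models = [
            anneal(train_cm, age.loc[train_ids], train_survey, cfg, seed=base + i)
            for i in range(models_per_fold)
        ]
        clock = build_ensemble(models, top_k=models_per_fold,
                               cluster_matrix=train_cm,
                               provenance={"fold": f, "base_seed": base})
        train_raw = predict(clock, train_cm)["raw_age"]
        clock.rotation = fit_rotation(train_raw, age.loc[train_ids])
        fold_clocks.append(clock)

        fold_pred = predict(clock, cluster_matrix.subset_samples(test_ids),
                            ages=age.loc[test_ids])
        fold_pred["fold"] = f
        preds.append(fold_pred)

    predictions = pd.concat(preds).loc[cluster_matrix.sample_ids]
    return CrossValidationResult(predictions, fold_clocks, assignment)
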