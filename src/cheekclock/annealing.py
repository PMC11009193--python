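"""Simulated-annealing search for multi-objective epigenetic age models.

The search space is the set of cluster subsets.  For each candidate subset a
linear age model is fitted by ordinary least squares, and the subset is
scored by a weighted sum of three terms (lower is better):

``total = w_rmse * RMSE  +  w_sig * sum_f log10 p_f  +  w_cplx * n_clusters``

where ``p_f`` is the two-sided Pearson-correlation test p-value between delta
age (predicted minus chronological) and lifestyle/health factor ``f``.  The
significance term is negative when associations are strong, so the search is
simultaneously pulled toward accurate models and toward models whose age
deviations carry lifestyle signal — the defining trade-off of this clock
family.  Moves (add / drop / swap one cluster) are accepted by the Metropolis
rule under a geometrically cooled temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .clustering import ClusterMatrix
from .datatypes import SurveyTable

__all__ = [
    "ClockModel",
    "AnnealConfig",
    "metropolis_accept",
    "fit_weights",
    "delta_age_pvalues",
    "score_model",
    "anneal",
    "train_many",
    "P_FLOOR",
]

#: p-values are floored here before log10 so a perfect correlation cannot
#: inject -inf into the objective.
P_FLOOR = 1e-300


@dataclass
class ClockModel:
    """One annealed linear age model over a cluster subset."""

    cluster_ids: list[str]
    weights: np.ndarray
    intercept: float
    score_components: dict[str, float]
    total_score: float
    train_seed: int | None = None

    def predict(self, cluster_values: pd.DataFrame) -> pd.Series:
        """Linear prediction from a clusters × samples value frame."""
        X = cluster_values.loc[self.cluster_ids].to_numpy(dtype=float).T
        return pd.Series(self.intercept + X @ self.weights,
                         index=cluster_values.columns, name="predicted_age")

    def to_dict(self) -> dict:
        return {
            "cluster_ids": list(self.cluster_ids),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "score_components": {k: float(v) for k, v in self.score_components.items()},
            "total_score": float(self.total_score),
            "train_seed": self.train_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            cluster_ids=list(d["cluster_ids"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            score_components=dict(d["score_components"]),
            total_score=float(d["total_score"]),
            train_seed=d.get("train_seed"),
        )


@dataclass
class AnnealConfig:
    """Hyperparameters of the annealing search.

    ``w_rmse`` / ``w_sig`` / ``w_cplx`` weight the accuracy, significance and
    complexity terms; ``factors=None`` means every lifestyle column of the
    survey enters the significance term.  ``sig_floor`` saturates each
    factor's evidence inside the objective: p-values are clipped there before
    the log, so one overwhelming association cannot drown out the accuracy
    term — beyond ~10 orders of magnitude, more significance is not more
    information about a cohort of this size.  ``t0=None`` auto-calibrates the
    starting temperature so that roughly ``warmup_accept`` of worsening moves
    would be accepted over a short random-walk warm-up.
    """

    w_rmse: float = 1.0
    w_sig: float = 1.0
    w_cplx: float = 0.5
    sig_floor: float = 1e-10
    factors: list[str] | None = None
    iterations: int = 2000
    t0: float | None = None
    cooling: float = 0.995
    t_min: float = 1e-9
    p_add: float = 0.3
    p_drop: float = 0.3
    p_swap: float = 0.4
    max_model_size: int = 15
    init_size: int = 3
    warmup_moves: int = 100
    warmup_accept: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        if abs(self.p_add + self.p_drop + self.p_swap - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.max_model_size < 1 or self.init_size < 1:
            raise ValueError("model sizes must be >= 1")
        if not 0.0 < self.warmup_accept < 1.0:
            raise ValueError("warmup_accept must lie in (0, 1)")


def metropolis_accept(delta_score: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """The annealer's acceptance rule.

    Improving or equal moves (``delta_score <= 0``) are always accepted;
    worsening moves with probability ``exp(-delta_score / temperature)``.
    """
    if delta_score <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_score / temperature))


def fit_weights(cluster_values: pd.DataFrame | np.ndarray, ages) -> tuple[np.ndarray, float]:
    """Ordinary least squares of age on the selected cluster averages.

    ``cluster_values`` is clusters × samples (or samples × clusters ndarray
    transposed by the caller — a DataFrame is always clusters × samples).
    Returns ``(weights, intercept)``; rank-deficient designs fall back to the
    minimum-norm solution with a warning.
    """
    if isinstance(cluster_values, pd.DataFrame):
        X = cluster_values.to_numpy(dtype=float).T
    else:
        X = np.asarray(cluster_values, dtype=float)
    y = np.asarray(ages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in the restricted cluster matrix")
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} samples to fit {k} clusters")
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1:
        warnings.warn("rank-deficient design; minimum-norm solution used")
    return coef[1:], float(coef[0])


class _FactorBlock:
    """Pre-centred lifestyle factors for fast repeated correlation testing.

    When ``ages`` is supplied, factors are residualised against age once and
    every delta is residualised on the fly, so the tests are partial
    correlations controlling for age.  Inside the training objective this is
    essential: a badly fitting model's delta is dominated by ``-age`` and
    would otherwise harvest spurious significance from every age-correlated
    factor.
    """

    def __init__(self, survey: SurveyTable, factors: list[str] | None,
                 ages=None):
        names = list(factors) if factors is not None else list(survey.lifestyle.columns)
        missing = [f for f in names if f not in survey.lifestyle.columns]
        if missing:
            raise KeyError(f"unknown lifestyle factors: {missing}")
        self.names = names
        F = survey.lifestyle[names].to_numpy(dtype=float)
        self.F = F
        self.mask = np.isfinite(F)
        self.complete = bool(self.mask.all())
        self.n = F.shape[0]
        self.age = None
        if ages is not None:
            a = np.asarray(ages, dtype=float)
            if len(a) != self.n:
                raise ValueError("ages length does not match survey")
            ac = a - a.mean()
            denom = float(ac @ ac)
            self.age = ac if denom > 0 else None
            self._age_denom = denom
        if self.complete:
            Fc = F - F.mean(axis=0)
            if self.age is not None:
                Fc = Fc - np.outer(self.age, (self.age @ Fc) / self._age_denom)
            self.Fc = Fc
            self.Fnorm = np.sqrt((Fc**2).sum(axis=0))

    @property
    def df(self) -> int:
        # one df lost to the mean, one more to the age adjustment
        return self.n - (3 if self.age is not None else 2)

    def _residualise(self, v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        if self.age is not None:
            vc = vc - self.age * float(self.age @ vc) / self._age_denom
        return vc

    def pvalues(self, delta: np.ndarray) -> np.ndarray:
        """Two-sided (partial) Pearson-test p per factor, pairwise-complete."""
        if self.complete:
            dc = self._residualise(delta)
            dn = math.sqrt(float(dc @ dc))
            if dn == 0:
                warnings.warn("zero-variance delta; lifestyle p-values set to 1")
                return np.ones(len(self.names))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (dc @ self.Fc) / (dn * self.Fnorm)
            p = _r_to_p(r, self.df)
            zero_var = self.Fnorm == 0
            if zero_var.any():
                warnings.warn("zero-variance factor; its p-value set to 1")
                p[zero_var] = 1.0
            return p
        out = np.ones(len(self.names))
        for j in range(len(self.names)):
            ok = self.mask[:, j] & np.isfinite(delta)
            if ok.sum() < 4:
                continue
            x, y = delta[ok], self.F[ok, j]
            if self.age is not None:
                a = self.age[ok]
                denom = float(a @ a)
                if denom > 0:
                    x = x - x.mean() - a * float(a @ (x - x.mean())) / denom
                    y = y - y.mean() - a * float(a @ (y - y.mean())) / denom
            if x.std() == 0 or y.std() == 0:
                warnings.warn("zero-variance pair; p-value set to 1")
                continue
            r = np.corrcoef(x, y)[0, 1]
            dfree = ok.sum() - (3 if self.age is not None else 2)
            out[j] = float(_r_to_p(np.array([r]), dfree)[0])
        return out


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for a (partial) Pearson r with ``df`` error degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-323))
    p = 2.0 * t_dist.sf(np.abs(t), df=df)
    return np.clip(p, P_FLOOR, 1.0)


def delta_age_pvalues(
    delta, survey: SurveyTable, factors: list[str] | None = None, ages=None
) -> pd.Series:
    """Per-factor two-sided Pearson-correlation p-values for delta age.

    With ``ages`` supplied the tests are partial correlations controlling for
    chronological age (the form used inside the training objective);
    otherwise plain Pearson tests.  Pairwise-complete over missing entries; a
    zero-variance factor yields p = 1 with a warning (never NaN).  p-values
    are floored at ``P_FLOOR``.
    """
    block = _FactorBlock(survey, factors, ages=ages)
    d = np.asarray(delta, dtype=float)
    if d.shape[0] != block.n:
        raise ValueError("delta length does not match survey")
    return pd.Series(block.pvalues(d), index=block.names, name="p")


def _components(pred: np.ndarray, ages: np.ndarray, block: _FactorBlock,
                n_clusters: int, cfg: AnnealConfig) -> tuple[dict[str, float], float]:
    rmse = float(np.sqrt(np.mean((pred - ages) ** 2)))
    p = block.pvalues(pred - ages)
    lifestyle = float(np.log10(np.clip(p, max(cfg.sig_floor, P_FLOOR), 1.0)).sum())
    comps = {
        "rmse_term": rmse,
        "lifestyle_term": lifestyle,
        "complexity_term": float(n_clusters),
    }
    total = cfg.w_rmse * rmse + cfg.w_sig * lifestyle + cfg.w_cplx * n_clusters
    return comps, total


def score_model(
    model: ClockModel,
    cluster_matrix: ClusterMatrix,
    ages,
    survey: SurveyTable,
    config: AnnealConfig | None = None,
) -> ClockModel:
    """Score a fitted model; returns a copy with components and total filled in."""
    if len(model.cluster_ids) == 0:
        raise ValueError("cannot score an empty model")
    cfg = config or AnnealConfig()
    y = np.asarray(ages, dtype=float)
    block = _FactorBlock(survey, cfg.factors, ages=y)
    pred = model.predict(cluster_matrix.values).to_numpy()
    comps, total = _components(pred, y, block, len(model.cluster_ids), cfg)
    return ClockModel(model.cluster_ids, model.weights, model.intercept,
                      comps, total, model.train_seed)


def _fit_and_score(X: np.ndarray, subset: np.ndarray, y: np.ndarray,
                   block: _FactorBlock, cfg: AnnealConfig):
    """OLS fit + objective for one subset (columns of X). Returns everything."""
    Xs = X[:, subset]
    n = X.shape[0]
    design = np.column_stack([np.ones(n), Xs])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    comps, total = _components(pred, y, block, len(subset), cfg)
    return coef[1:], float(coef[0]), comps, total


def anneal(
    cluster_matrix: ClusterMatrix,
    ages,
    survey: SurveyTable,
    config: AnnealConfig | None = None,
    seed: int = 0,
    return_trace: bool = False,
):
    """Run one simulated-annealing search; returns the best model ever seen.

    Starting from a random subset of ``init_size`` clusters, each iteration
    proposes adding, dropping or swapping one cluster, refits the OLS weights
    and rescores.  Improving moves are always accepted; worsening moves with
    probability ``exp(-dS / T)`` under geometric cooling ``T <- cooling * T``.
    Identical seeds give identical trajectories.

    With ``return_trace=True`` also returns a DataFrame of (iteration,
    temperature, current_score, best_score).
    """
    cfg = config or AnnealConfig()
    rng = np.random.default_rng(seed)
    values = cluster_matrix.values
    ids = list(values.index)
    C = len(ids)
    if C < 2:
        raise ValueError("need at least 2 clusters to search over")
    X = values.to_numpy(dtype=float).T  # samples × clusters
    y = np.asarray(ages, dtype=float)
    usable = ~np.isnan(X).all(axis=0)   # all-missing clusters are unproposable
    if np.isnan(X[:, usable]).any():
        raise ValueError("cluster matrix has partial missing values; impute first")
    usable_idx = np.flatnonzero(usable)
    if len(usable_idx) < 2:
        raise ValueError("fewer than 2 usable clusters")
    block = _FactorBlock(survey, cfg.factors, ages=y)
    max_size = min(cfg.max_model_size, len(usable_idx), X.shape[0] - 2)

    init_size = min(cfg.init_size, max_size)
    current = rng.choice(usable_idx, size=init_size, replace=False)
    cur_w, cur_b, cur_comps, cur_score = _fit_and_score(X, current, y, block, cfg)

    def _propose(subset: np.ndarray) -> np.ndarray | None:
        inside = set(subset.tolist())
        outside = np.array([i for i in usable_idx if i not in inside])
        move = rng.choice(3, p=[cfg.p_add, cfg.p_drop, cfg.p_swap])
        if move == 0 and (len(subset) >= max_size or len(outside) == 0):
            return None
        if move == 1 and len(subset) <= 1:
            return None
        if move == 2 and len(outside) == 0:
            return None
        if move == 0:
            return np.append(subset, rng.choice(outside))
        if move == 1:
            drop = rng.integers(len(subset))
            return np.delete(subset, drop)
        swap = rng.integers(len(subset))
        out = subset.copy()
        out[swap] = rng.choice(outside)
        return out

    # temperature: auto-calibrate on a short random walk so that worsening
    # moves start out mostly accepted
    if cfg.t0 is None:
        walk = current.copy()
        walk_score = cur_score
        worsen: list[float] = []
        for _ in range(cfg.warmup_moves):
            cand = _propose(walk)
            if cand is None:
                continue
            _, _, _, s = _fit_and_score(X, cand, y, block, cfg)
            if s > walk_score:
                worsen.append(s - walk_score)
            walk, walk_score = cand, s
        mean_up = float(np.mean(worsen)) if worsen else 1.0
        T = mean_up / (-math.log(cfg.warmup_accept))
    else:
        T = cfg.t0
    T = max(T, cfg.t_min)
    t0_used = T

    best = (current.copy(), cur_w, cur_b, cur_comps, cur_score)
    trace = np.empty((cfg.iterations, 4))
    for it in range(cfg.iterations):
        cand = _propose(current)
        if cand is not None:
            w, b, comps, s = _fit_and_score(X, cand, y, block, cfg)
            if metropolis_accept(s - cur_score, T, rng):
                current, cur_w, cur_b, cur_comps, cur_score = cand, w, b, comps, s
                if s < best[4]:
                    best = (cand.copy(), w, b, comps, s)
        trace[it] = (it, T, cur_score, best[4])
        T = max(T * cfg.cooling, cfg.t_min)

    subset, w, b, comps, s = best
    model = ClockModel(
        cluster_ids=[ids[i] for i in subset],
        weights=np.asarray(w, dtype=float),
        intercept=b,
        score_components=comps,
        total_score=s,
        train_seed=seed,
    )
    if return_trace:
        tdf = pd.DataFrame(trace, columns=["iteration", "temperature",
                                           "current_score", "best_score"])
        tdf.attrs["t0"] = t0_used
        return model, tdf
    return model


def train_many(
    cluster_matrix: ClusterMatrix,
    ages,
    survey: SurveyTable,
    config: AnnealConfig | None = None,
    n_models: int = 1098,
    base_seed: int = 0,
) -> list[ClockModel]:
    """Repeat the annealing search ``n_models`` times with seeds base_seed + i.

    Each run is independent, so results do not depend on execution order; the
    default repeat count matches the production-scale training protocol.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return [
        anneal(cluster_matrix, ages, survey, config, seed=base_seed + i)
        for i in range(n_models)
    ]
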