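"""Clock evaluation: metric suite, delta-age association model, baseline.

Metrics follow the buccal-clock reporting convention: RMSE, MAE, R²
(squared Pearson correlation), MAB (mean absolute bias — the mean absolute
deviation of the fitted prediction-vs-age line from the identity line, an
indicator of systematic age compression/expansion), and MRE (mean replicate
error from the mean — a test-retest reliability measure over replicate
sample groups).

The delta-age association model regresses delta age on all lifestyle,
demographic, technical (and optionally cell-proportion) covariates at once,
so each factor's significance is estimated with the others held constant,
with Benjamini–Hochberg control across factors.  The penalized-regression
baseline is the first-generation comparator: an elastic net trained for
accuracy alone, against which the multi-objective clock's lifestyle
advantage is demonstrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from sklearn.linear_model import ElasticNetCV
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .annealing import P_FLOOR
from .clustering import ClusterMatrix
from .datatypes import SurveyTable
from .ensemble import _replicate_aware_folds

__all__ = [
    "MetricReport",
    "compute_metrics",
    "bh_fdr",
    "delta_age_model",
    "build_covariate_frame",
    "baseline_penalized_cv",
    "BaselineResult",
]


@dataclass
class MetricReport:
    rmse: float
    mae: float
    r2: float | None
    mab: float
    mre: float | None = None

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2,
                "mab": self.mab, "mre": self.mre}


def compute_metrics(predictions, ages, replicate_groups: pd.Series | None = None) -> MetricReport:
    """Compute the five-clock-metric report.

    ``mab`` fits prediction on age by least squares and averages the absolute
    deviation of the fitted line from the identity over the observed ages;
    ``mre`` averages, over all replicate samples, the absolute deviation of
    each sample's prediction from its replicate-group mean prediction.
    """
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(ages, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 samples")
    if len(pred) != len(age):
        raise ValueError("predictions and ages differ in length")
    err = pred - age
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(pred) == 0 or np.std(age) == 0:
        warnings.warn("zero variance; r2 undefined and reported as missing")
        r2 = None
    else:
        r2 = float(pearsonr(pred, age)[0] ** 2)
    slope, intercept = np.polyfit(age, pred, deg=1)
    mab = float(np.mean(np.abs(intercept + slope * age - age)))

    mre = None
    if replicate_groups is not None:
        groups = pd.Series(replicate_groups).dropna()
        sizes = groups.value_counts()
        if (sizes < 2).any():
            raise ValueError("replicate groups must have size >= 2")
        if len(groups):
            pred_s = pd.Series(pred, index=pd.Series(replicate_groups).index)
            dev = []
            for gid, members in groups.groupby(groups).groups.items():
                vals = pred_s.loc[members]
                dev.extend(np.abs(vals - vals.mean()).tolist())
            mre = float(np.mean(dev))
    return MetricReport(rmse=rmse, mae=mae, r2=r2, mab=mab, mre=mre)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_covariate_frame(
    survey: SurveyTable, cell_proportions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Numeric design frame: lifestyle + demographics + one-hot categoricals
    and technicals (first level as reference) + optional cell proportions."""
    parts = [survey.lifestyle, survey.demographics]
    for df in (survey.categorical, survey.technical):
        if not len(df.columns):
            continue
        num = df.select_dtypes(include=[np.number])
        cat = df.drop(columns=num.columns)
        if len(num.columns):
            parts.append(num.astype(float))
        if len(cat.columns):
            parts.append(pd.get_dummies(cat.astype(str), drop_first=True, dtype=float))
    if cell_proportions is not None:
        # drop one column: proportions sum to 1 and would alias the constant
        parts.append(cell_proportions.iloc[:, 1:].astype(float))
    out = pd.concat([p for p in parts if len(p.columns)], axis=1)
    return out.astype(float)


def delta_age_model(delta, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS of delta age on all covariates jointly, with BH-adjusted q-values.

    Aliased (linearly dependent) columns are dropped greedily with a warning
    before fitting.  Returns a DataFrame indexed by covariate with columns
    ``coef``, ``se``, ``p``, ``q``.
    """
    y = np.asarray(delta, dtype=float)
    X = covariates.astype(float)
    if len(y) != len(X):
        raise ValueError("delta and covariates differ in length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more samples than covariates")

    keep: list[str] = []
    base = np.ones((len(y), 1))
    current = base
    for col in X.columns:
        cand = np.column_stack([current, X[col].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(current):
            keep.append(col)
            current = cand
        else:
            warnings.warn(f"covariate {col!r} is aliased and was dropped")
    design = sm.add_constant(X[keep])
    fit = sm.OLS(y, design).fit()
    res = pd.DataFrame(
        {
            "coef": fit.params.drop("const"),
            "se": fit.bse.drop("const"),
            "p": fit.pvalues.drop("const").clip(lower=P_FLOOR),
        }
    )
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res


@dataclass
class BaselineResult:
    """Elastic-net comparator output: OOF predictions, metrics, factor tests."""

    predictions: pd.DataFrame        # sample × {predicted_age, delta_age, fold}
    metrics: "MetricReport"
    factor_tests: pd.DataFrame       # factor × {r, p, q}


def baseline_penalized_cv(
    cluster_matrix: ClusterMatrix,
    ages,
    survey: SurveyTable,
    folds: int = 10,
    l1_ratio: float = 0.5,
    seed: int = 0,
    alphas=50,
) -> BaselineResult:
    """First-generation comparator: elastic net under cross-validation.

    Per outer fold the penalty is chosen by inner cross-validation on the
    training split; out-of-fold predictions, the metric report, and per-factor
    delta-age Pearson tests (BH-adjusted) are returned so the annealed clock's
    lifestyle association can be compared head-to-head.
    """
    rng = np.random.default_rng(seed)
    age = pd.Series(np.asarray(ages, dtype=float), index=cluster_matrix.sample_ids)
    assignment = _replicate_aware_folds(survey, folds, rng)
    X = cluster_matrix.values.T  # samples × clusters
    if X.isna().any().any():
        raise ValueError("cluster matrix contains missing values")

    preds = []
    for f in range(folds):
        test_ids = assignment.index[assignment == f].tolist()
        train_ids = assignment.index[assignment != f].tolist()
        if len(test_ids) == 0:
            raise ValueError(f"fold {f} is empty; reduce the number of folds")
        scaler = StandardScaler().fit(X.loc[train_ids])
        enet = ElasticNetCV(l1_ratio=l1_ratio, cv=5, alphas=alphas,
                            random_state=int(seed) % (2**31), max_iter=5000)
        enet.fit(scaler.transform(X.loc[train_ids]), age.loc[train_ids])
        yhat = enet.predict(scaler.transform(X.loc[test_ids]))
        fold_pred = pd.DataFrame(
            {"predicted_age": yhat,
             "delta_age": yhat - age.loc[test_ids].to_numpy(),
             "fold": f},
            index=pd.Index(test_ids),
        )
        preds.append(fold_pred)
    predictions = pd.concat(preds).loc[cluster_matrix.sample_ids]

    metrics = compute_metrics(
        predictions["predicted_age"], age,
        replicate_groups=survey.replicate_group,
    )
    rows = {}
    for factor in survey.lifestyle.columns:
        v = survey.lifestyle[factor].to_numpy(dtype=float)
        d = predictions["delta_age"].to_numpy()
        ok = np.isfinite(v) & np.isfinite(d)
        if ok.sum() < 3 or np.std(v[ok]) == 0:
            rows[factor] = (np.nan, 1.0)
            continue
        r, p = pearsonr(d[ok], v[ok])
        rows[factor] = (r, max(p, P_FLOOR))
    tests = pd.DataFrame(rows, index=["r", "p"]).T
    tests["q"] = bh_fdr(tests["p"].to_numpy())
    return BaselineResult(predictions, metrics, tests)
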