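"""Probe quality filtering, sex prediction, cell deconvolution, PCA diagnostic.

These stages consume matrices (not raw array intensities): quality filtering
is rule-based and fully reported, sex is called from methylation-derived
summaries of the X and Y chromosomes, cell-type proportions are recovered by
constrained least squares against reference profiles, and the PCA diagnostic
reports how survey and technical variables load on the leading components of
the cluster-averaged inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .clustering import ClusterMatrix
from .datatypes import MethylationMatrix, ProbeManifest, SurveyTable

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "filter_probes",
    "predict_sex",
    "estimate_cell_proportions",
    "pca_diagnostic",
    "PCADiagnostic",
]


@dataclass
class FilterThresholds:
    """Probe-filter settings; rules run in a fixed, reported order."""

    exclude_probes: tuple[str, ...] = ()       # cross-reactive / SNP lists
    detection_p: float = 0.01                  # per-cell detection cutoff
    detection_max_fail: float = 0.05           # max fraction of failing samples
    max_missing: float = 0.2                   # max fraction of missing cells
    drop_sex_chromosomes: bool = True
    min_variance: float = 1e-4                 # on the provided scale


#: Rule application order (fixed):
FILTER_RULES = ("exclusion_list", "detection_p", "missingness",
                "sex_chromosomes", "variance")


@dataclass
class FilterReport:
    """Accounting of the sequential filter: removals per rule + survivors."""

    removed: dict[str, list[str]]
    surviving: list[str]
    thresholds: FilterThresholds

    @property
    def removed_counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    def total_input(self) -> int:
        return len(self.surviving) + sum(len(v) for v in self.removed.values())


def filter_probes(
    matrix: MethylationMatrix,
    manifest: ProbeManifest | None = None,
    qc: pd.DataFrame | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the sequential probe-quality filter.

    Rules, in order: explicit exclusion list; detection-p failures (skipped
    with a warning when ``qc`` is absent); missingness; sex chromosomes
    (skipped when no manifest); low variance.  Every input probe lands in
    exactly one bucket: removed-under-one-rule or surviving.
    """
    th = thresholds or FilterThresholds()
    removed: dict[str, list[str]] = {rule: [] for rule in FILTER_RULES}
    current = matrix.values

    excl = set(th.exclude_probes) & set(current.index)
    removed["exclusion_list"] = sorted(excl)
    current = current.drop(index=list(excl))

    if qc is not None:
        qc_sub = qc.reindex(index=current.index, columns=current.columns)
        fail_frac = (qc_sub > th.detection_p).mean(axis=1)
        bad = current.index[fail_frac > th.detection_max_fail]
        removed["detection_p"] = bad.tolist()
        current = current.drop(index=bad)
    else:
        warnings.warn("no detection p-values supplied; detection-p rule skipped")

    miss_frac = current.isna().mean(axis=1)
    bad = current.index[miss_frac > th.max_missing]
    removed["missingness"] = bad.tolist()
    current = current.drop(index=bad)

    if th.drop_sex_chromosomes and manifest is not None:
        sex_probes = manifest.table.index[
            manifest.table["chrom"].astype(str).isin(["X", "Y"])
        ]
        bad = current.index.intersection(sex_probes)
        removed["sex_chromosomes"] = bad.tolist()
        current = current.drop(index=bad)

    var = current.var(axis=1, ddof=1)
    bad = current.index[var.fillna(0.0) < th.min_variance]
    removed["variance"] = bad.tolist()
    current = current.drop(index=bad)

    if current.shape[0] == 0:
        raise ValueError("all probes removed by filtering; relax thresholds")
    report = FilterReport(removed=removed, surviving=current.index.tolist(),
                          thresholds=th)
    return MethylationMatrix(current, matrix.scale), report


def predict_sex(
    matrix: MethylationMatrix,
    manifest: ProbeManifest,
    y_signal_floor: float = 0.0,
    margin: float = 0.2,
) -> pd.Series:
    """Call per-sample sex from X/Y methylation summaries.

    The per-sample score is the fraction of Y-chromosome probes whose M value
    exceeds ``y_signal_floor`` (XY-like samples carry Y signal; XX-like
    samples show only background).  Scores are split by exact two-class 1-D
    clustering (the split minimising within-class sum of squares); samples
    within ``margin`` × (class-mean gap) of the boundary are labelled
    ``undetermined``.  The X-chromosome median M is used to orient the call
    when the Y separation is degenerate.
    """
    work = matrix.to_m() if matrix.scale == "beta" else matrix
    x_probes = manifest.probes_on("X").intersection(work.probe_ids)
    y_probes = manifest.probes_on("Y").intersection(work.probe_ids)
    if len(x_probes) == 0 or len(y_probes) == 0:
        raise ValueError("sex prediction requires X and Y chromosome probes")

    score = (work.values.loc[y_probes] > y_signal_floor).mean(axis=0)
    s = score.to_numpy(dtype=float)
    order = np.argsort(s, kind="stable")
    ss = s[order]
    n = len(ss)

    # exact 1-D 2-means: best split point over the sorted scores
    best_cut, best_cost = 1, np.inf
    csum = np.concatenate([[0.0], np.cumsum(ss)])
    csq = np.concatenate([[0.0], np.cumsum(ss**2)])
    for cut in range(1, n):
        left = csq[cut] - csum[cut] ** 2 / cut
        right = (csq[n] - csq[cut]) - (csum[n] - csum[cut]) ** 2 / (n - cut)
        if left + right < best_cost:
            best_cost, best_cut = left + right, cut
    lo_mean = csum[best_cut] / best_cut
    hi_mean = (csum[n] - csum[best_cut]) / (n - best_cut)
    boundary = 0.5 * (lo_mean + hi_mean)
    gap = hi_mean - lo_mean

    labels = pd.Series("undetermined", index=work.sample_ids, dtype=object)
    if gap <= 1e-12:
        return labels  # no separation at all
    confident = np.abs(s - boundary) >= margin * gap
    labels[(s > boundary) & confident] = "XY-like"
    labels[(s < boundary) & confident] = "XX-like"
    return labels


def estimate_cell_proportions(
    matrix: MethylationMatrix, reference: pd.DataFrame
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions by constrained least squares.

    ``reference`` holds per-cell-type baseline M profiles (probes × types).
    For each sample the nonnegative least-squares problem with a sum-to-one
    constraint is solved (NNLS on a penalty-augmented system, then exact
    renormalisation).  Returns samples × types proportions.
    """
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least 2 cell types")
    missing = reference.index.difference(matrix.probe_ids)
    if len(missing):
        raise KeyError(f"reference probes absent from matrix: {missing.tolist()[:5]}")
    work = matrix.to_m() if matrix.scale == "beta" else matrix
    R = reference.to_numpy(dtype=float)
    lam = 100.0 * max(1.0, np.abs(R).mean())
    A = np.vstack([R, lam * np.ones((1, R.shape[1]))])
    out = np.zeros((work.n_samples, R.shape[1]))
    X = work.values.loc[reference.index].to_numpy(dtype=float)
    for j in range(work.n_samples):
        x = X[:, j]
        ok = np.isfinite(x)
        if not ok.all():
            Aj = np.vstack([R[ok], lam * np.ones((1, R.shape[1]))])
            b = np.concatenate([x[ok], [lam]])
            w, _ = nnls(Aj, b)
        else:
            w, _ = nnls(A, np.concatenate([x, [lam]]))
        total = w.sum()
        out[j] = w / total if total > 0 else np.full(R.shape[1], 1.0 / R.shape[1])
    return pd.DataFrame(out, index=work.sample_ids, columns=reference.columns)


@dataclass
class PCADiagnostic:
    """Top-k PC scores plus factor-PC correlation and p-value tables."""

    scores: pd.DataFrame          # samples × PC1..PCk
    explained_variance_ratio: np.ndarray
    correlations: pd.DataFrame    # variables × PCs, Pearson r
    pvalues: pd.DataFrame         # variables × PCs


def _numeric_survey_frame(survey: SurveyTable) -> pd.DataFrame:
    """All survey variables as numeric columns (categoricals as codes)."""
    parts = [survey.age.rename("age").to_frame(), survey.lifestyle,
             survey.demographics]
    for df in (survey.categorical, survey.technical):
        if not len(df):
            continue
        enc = {}
        for col in df.columns:
            s = df[col]
            enc[col] = s.astype(float) if pd.api.types.is_numeric_dtype(s) \
                else pd.factorize(s, sort=True)[0].astype(float)
        parts.append(pd.DataFrame(enc, index=df.index))
    return pd.concat([p for p in parts if len(p)], axis=1)


def pca_diagnostic(
    cluster_matrix: ClusterMatrix, survey: SurveyTable, k: int = 18
) -> PCADiagnostic:
    """PCA of cluster-averaged inputs with factor-PC correlation screening.

    Used as an intermediate check that age, lifestyle and technical structure
    is present in the model inputs before any training happens.
    """
    data = cluster_matrix.values.T.to_numpy(dtype=float)  # samples × clusters
    n, d = data.shape
    if k > min(n - 1, d):
        raise ValueError(f"k={k} exceeds the data rank bound {min(n - 1, d)}")
    if np.isnan(data).any():
        raise ValueError("cluster matrix contains missing values")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)
    pc_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=cluster_matrix.sample_ids, columns=pc_names)

    variables = _numeric_survey_frame(survey).loc[scores_df.index]
    corr = pd.DataFrame(index=variables.columns, columns=pc_names, dtype=float)
    pval = pd.DataFrame(index=variables.columns, columns=pc_names, dtype=float)
    for var in variables.columns:
        v = variables[var].to_numpy(dtype=float)
        ok = np.isfinite(v)
        for pc in pc_names:
            u = scores_df[pc].to_numpy()
            if ok.sum() < 3 or np.std(v[ok]) == 0:
                corr.loc[var, pc], pval.loc[var, pc] = np.nan, 1.0
                continue
            r, p = pearsonr(v[ok], u[ok])
            corr.loc[var, pc], pval.loc[var, pc] = r, p
    return PCADiagnostic(scores_df, pca.explained_variance_ratio_, corr, pval)
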