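"""Descriptive methylome analyses: trajectories, overlaps, enrichment.

These are the downstream biology readouts: how CpG means and variances move
across chronological-age bins, which CpGs the different lifestyle/health
factors share among their most-correlated sets, whether a CpG set is
enriched in island/shore/shelf/open-sea genomic context, and which CpGs are
differentially variable between low- and high-delta-age subcohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ISLAND_RELATIONS, MethylationMatrix, ProbeManifest
from .evaluation import bh_fdr

__all__ = [
    "BinProfile",
    "split_by_delta",
    "binned_profile",
    "select_by_correlation",
    "factor_correlation_overlap",
    "context_enrichment",
    "differential_variability",
]


def split_by_delta(delta: pd.Series, low: float = -5.0, high: float = 5.0):
    """Split samples into low / high delta-age subcohorts.

    Defaults follow the convention of contrasting samples predicted more than
    five years younger than their chronological age against those predicted
    more than five years older.  Returns ``(low_ids, high_ids)``.
    """
    d = pd.Series(delta)
    return d.index[d < low].tolist(), d.index[d > high].tolist()


@dataclass
class BinProfile:
    """Per-CpG, per-age-bin statistic with its trend against bin midpoints."""

    bin_edges: np.ndarray          # n_bins + 1, years
    statistic: str                 # "mean" or "variance"
    values: pd.DataFrame           # probes × bins
    correlation: pd.Series         # per-probe Pearson r vs bin midpoint

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def binned_profile(
    matrix: MethylationMatrix, ages, n_bins: int = 15, statistic: str = "mean"
) -> BinProfile:
    """Equal-width age bins over the observed range; statistic per CpG per bin.

    The default of 15 bins spans an adult cohort in roughly 5-year steps.
    Each bin needs >= 2 samples (>= 3 for variance).  Per CpG, the Pearson r
    of the statistic against bin midpoints summarises the trajectory; a
    constant trajectory has undefined r, reported as missing.
    """
    if statistic not in ("mean", "variance"):
        raise ValueError("statistic must be 'mean' or 'variance'")
    age = np.asarray(ages, dtype=float)
    if len(age) != matrix.n_samples:
        raise ValueError("ages length does not match sample count")
    edges = np.linspace(age.min(), age.max(), n_bins + 1)
    which = np.clip(np.digitize(age, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    needed = 2 if statistic == "mean" else 3
    if (counts < needed).any():
        raise ValueError(
            f"bin(s) with fewer than {needed} samples; use fewer bins"
        )
    vals = matrix.values.to_numpy(dtype=float)
    cols = []
    for b in range(n_bins):
        sub = vals[:, which == b]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat = (np.nanmean(sub, axis=1) if statistic == "mean"
                    else np.nanvar(sub, axis=1, ddof=1))
        cols.append(stat)
    table = pd.DataFrame(
        np.column_stack(cols), index=matrix.probe_ids,
        columns=[f"bin{b:02d}" for b in range(n_bins)],
    )
    mid = 0.5 * (edges[:-1] + edges[1:])
    midc = mid - mid.mean()
    V = table.to_numpy()
    Vc = V - V.mean(axis=1, keepdims=True)
    denom = np.sqrt((Vc**2).sum(axis=1)) * np.sqrt((midc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc @ midc) / denom
    corr = pd.Series(r, index=matrix.probe_ids, name="r")
    return BinProfile(edges, statistic, table, corr)


def select_by_correlation(
    profile: BinProfile, windows: list[tuple[float, float]] | None = None
) -> dict[tuple[float, float], pd.Index]:
    """CpG sets by |r| window of the binned trajectory.

    Defaults: mean mode selects the moderately correlated band
    ``[0.45, 0.55]`` and the near-perfect band ``[0.95, 1.0]``; variance mode
    selects ``|r| > 0.5``.  CpGs with undefined r never match.
    """
    if windows is None:
        windows = ([(0.45, 0.55), (0.95, 1.0)] if profile.statistic == "mean"
                   else [(0.5, 1.0)])
    absr = profile.correlation.abs()
    out = {}
    for lo, hi in windows:
        mask = (absr >= lo) & (absr <= hi)
        out[(lo, hi)] = profile.correlation.index[mask.fillna(False)]
    return out


def factor_correlation_overlap(
    values: pd.DataFrame, factors: pd.DataFrame, top_n: int = 100
) -> tuple[dict[str, pd.Index], pd.DataFrame]:
    """Top-|r| feature sets per factor and their pairwise overlap counts.

    ``values`` is features × samples (CpGs or clusters); ``factors`` is
    samples × factor columns (lifestyle/health plus age, sex, cell
    proportions, ...).  Per factor the ``top_n`` features by absolute Pearson
    correlation are taken (capped at the feature count with a warning); the
    returned matrix counts intersections and is symmetric by construction.
    """
    if not values.columns.equals(factors.index):
        factors = factors.loc[values.columns]
    n_feat = values.shape[0]
    if top_n > n_feat:
        warnings.warn(f"top_n={top_n} exceeds feature count {n_feat}; capped")
        top_n = n_feat
    V = values.to_numpy(dtype=float)
    Vc = V - V.mean(axis=1, keepdims=True)
    Vn = np.sqrt((Vc**2).sum(axis=1))
    sets: dict[str, pd.Index] = {}
    for factor in factors.columns:
        f = factors[factor].to_numpy(dtype=float)
        if np.std(f) == 0:
            raise ValueError(f"factor {factor!r} has zero variance")
        fc = f - f.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Vc @ fc) / (Vn * np.sqrt(fc @ fc))
        order = np.argsort(-np.abs(np.nan_to_num(r)), kind="stable")[:top_n]
        sets[factor] = values.index[order]
    names = list(factors.columns)
    overlap = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        sa = set(sets[a])
        for b in names:
            overlap.loc[a, b] = len(sa & set(sets[b]))
    return sets, overlap


def context_enrichment(
    cpg_set, background_set, manifest: ProbeManifest
) -> pd.DataFrame:
    """Island/Shore/Shelf/OpenSea enrichment of a CpG set by Fisher's exact test.

    For each category, the 2×2 table contrasts the set against the background
    excluding the set; returns per-category odds ratio, two-sided exact p,
    and BH-adjusted q across the four categories.  An empty category on both
    sides yields a missing odds ratio.
    """
    cpg_set = pd.Index(cpg_set)
    background_set = pd.Index(background_set)
    if not cpg_set.isin(background_set).all():
        raise ValueError("cpg_set must be a subset of background_set")
    unannotated = background_set.difference(manifest.probe_ids)
    if len(unannotated):
        raise KeyError(f"probes missing from manifest: {unannotated.tolist()[:5]}")
    rel = manifest.table["island_relation"]
    rest = background_set.difference(cpg_set)
    rows = []
    for cat in ISLAND_RELATIONS:
        a = int((rel.loc[cpg_set] == cat).sum())
        b = len(cpg_set) - a
        c = int((rel.loc[rest] == cat).sum())
        d = len(rest) - c
        if len(rest) == 0:
            # set equals background: the comparison is vacuous, no enrichment
            rows.append((cat, a, c, 1.0, 1.0))
            continue
        if (a + c) == 0:
            rows.append((cat, a, c, np.nan, 1.0))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cat, a, c, odds, p))
    out = pd.DataFrame(rows, columns=["category", "in_set", "in_background",
                                      "odds_ratio", "p"]).set_index("category")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def differential_variability(
    matrix: MethylationMatrix,
    group_low: list[str],
    group_high: list[str],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Differentially variable CpGs between delta-age extremes.

    ``group_low`` / ``group_high`` are sample-id lists (canonically delta age
    below -5 and above +5 years).  Per CpG a two-sided F-test compares the
    group variances; BH adjustment runs across all testable CpGs.  Returns
    per-CpG ``var_low``, ``var_high``, ``f_stat`` (high/low ratio), ``p``,
    ``q`` and the direction flags ``more_variable_high`` / ``_low`` at the
    ``q_cutoff``.
    """
    if len(group_low) < 3 or len(group_high) < 3:
        raise ValueError("both groups need at least 3 samples")
    lo = matrix.values[list(group_low)].to_numpy(dtype=float)
    hi = matrix.values[list(group_high)].to_numpy(dtype=float)
    n_lo, n_hi = lo.shape[1], hi.shape[1]
    var_lo = np.nanvar(lo, axis=1, ddof=1)
    var_hi = np.nanvar(hi, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = var_hi / var_lo
    testable = np.isfinite(f) & (var_lo > 0) & (var_hi > 0)
    p = np.full(len(f), np.nan)
    cdf = stats.f.cdf(f[testable], dfn=n_hi - 1, dfd=n_lo - 1)
    p[testable] = 2.0 * np.minimum(cdf, 1.0 - cdf)
    p[testable] = np.clip(p[testable], 0.0, 1.0)
    q = np.full(len(f), np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    out = pd.DataFrame(
        {"var_low": var_lo, "var_high": var_hi, "f_stat": f, "p": p, "q": q},
        index=matrix.probe_ids,
    )
    out["more_variable_high"] = (out["q"] < q_cutoff) & (out["f_stat"] > 1)
    out["more_variable_low"] = (out["q"] < q_cutoff) & (out["f_stat"] < 1)
    return out
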