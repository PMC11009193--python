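"""Core in-memory containers for methylation cohorts and beta/M conversions.

Conventions used throughout the package:

* Methylation matrices are probes-in-rows, samples-in-columns.
* Missing entries are ``NaN``; the boolean missing mask is derived, never stored.
* Beta values are methylation fractions in [0, 1]; M values are
  ``log2(beta / (1 - beta))``, the logit-scale representation that behaves
  better statistically near the 0/1 boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ProbeManifest",
    "SurveyTable",
    "ClusterMap",
    "beta_to_m",
    "m_to_beta",
    "ISLAND_RELATIONS",
]

#: The four genomic-context categories around CpG-dense regions.
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

# Array manifests ship six labels (N/S shore and shelf); we collapse to four.
_RELATION_ALIASES = {
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "Island": "Island",
    "Shore": "Shore",
    "Shelf": "Shelf",
    "OpenSea": "OpenSea",
}

_BETA_TOL = 1e-9


def beta_to_m(values, clip_eps: float = 1e-3):
    """Convert beta values to M values, ``M = log2(b / (1 - b))``.

    Betas are clipped to ``[clip_eps, 1 - clip_eps]`` first so the result is
    always finite.  NaNs pass through.
    """
    if not 0.0 < clip_eps < 0.5:
        raise ValueError(f"clip_eps must lie in (0, 0.5), got {clip_eps}")
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr, initial=0.0) < -_BETA_TOL or np.nanmax(arr, initial=1.0) > 1 + _BETA_TOL:
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, clip_eps, 1.0 - clip_eps)
    out = np.log2(clipped / (1.0 - clipped))
    out[np.isnan(arr)] = np.nan
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def m_to_beta(values):
    """Inverse of :func:`beta_to_m`: ``b = 2**M / (1 + 2**M)``."""
    arr = np.asarray(values, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class MethylationMatrix:
    """A probes × samples methylation grid with an explicit value scale.

    Parameters
    ----------
    values
        DataFrame with probe ids as index, sample ids as columns.  ``NaN``
        marks missing entries.
    scale
        ``"beta"`` or ``"m"``.
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "beta":
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -_BETA_TOL or finite.max() > 1 + _BETA_TOL):
                raise ValueError("beta-scale matrix contains values outside [0, 1]")
        else:
            if np.isinf(vals).any():
                raise ValueError("m-scale matrix contains non-finite values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_m(self, clip_eps: float = 1e-3) -> "MethylationMatrix":
        """Return an M-scale copy (identity if already on the M scale)."""
        if self.scale == "m":
            return MethylationMatrix(self.values.copy(), "m")
        return MethylationMatrix(beta_to_m(self.values, clip_eps), "m")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return MethylationMatrix(self.values.copy(), "beta")
        return MethylationMatrix(m_to_beta(self.values), "beta")

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        missing = pd.Index(probe_ids).difference(self.values.index)
        if len(missing):
            raise KeyError(f"probes absent from matrix: {missing.tolist()[:5]}")
        return MethylationMatrix(self.values.loc[list(probe_ids)], self.scale)


@dataclass
class ProbeManifest:
    """Per-probe annotation: chromosome, position, island relation, genes.

    ``table`` is indexed by probe id with columns ``chrom`` (str, including
    "X"/"Y"), ``pos`` (1-based bp), ``island_relation`` (one of
    :data:`ISLAND_RELATIONS`) and ``genes`` (list of symbols, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe")
        required = {"chrom", "pos", "island_relation", "genes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        rel = self.table["island_relation"].map(_RELATION_ALIASES)
        if rel.isna().any():
            bad = self.table["island_relation"][rel.isna()].unique().tolist()
            raise ValueError(f"unknown island_relation labels: {bad[:5]}")
        self.table = self.table.assign(island_relation=rel)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def probes_on(self, chrom: str) -> pd.Index:
        return self.table.index[self.table["chrom"].astype(str) == chrom]


@dataclass
class SurveyTable:
    """Per-sample survey and covariate data, all indexed by sample id.

    ``lifestyle`` holds the scaled (``[0, 1]``) responses to the lifestyle and
    health questions; ``demographics`` holds binary variables coded -1/+1;
    ``categorical`` and ``technical`` hold arbitrary covariates (e.g.
    race/ethnicity, education, plate, array position).  ``replicate_group``
    maps replicate samples to a shared group id (NaN elsewhere).
    """

    age: pd.Series
    lifestyle: pd.DataFrame
    demographics: pd.DataFrame = field(default_factory=pd.DataFrame)
    categorical: pd.DataFrame = field(default_factory=pd.DataFrame)
    technical: pd.DataFrame = field(default_factory=pd.DataFrame)
    replicate_group: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.age.index, "sample")
        if (self.age.dropna() < 0).any():
            raise ValueError("chronological_age must be >= 0")
        for name, df in (
            ("lifestyle", self.lifestyle),
            ("demographics", self.demographics),
            ("categorical", self.categorical),
            ("technical", self.technical),
        ):
            if len(df) and not df.index.equals(self.age.index):
                raise ValueError(f"{name} index does not match age index")
        ls = self.lifestyle.to_numpy(dtype=float)
        finite = ls[np.isfinite(ls)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("lifestyle responses must be scaled to [0, 1]")
        if len(self.demographics):
            dm = self.demographics.to_numpy(dtype=float)
            ok = np.isnan(dm) | (dm == -1) | (dm == 1)
            if not ok.all():
                raise ValueError("binary demographics must be coded -1 or +1")
        if self.replicate_group is not None:
            sizes = self.replicate_group.dropna().value_counts()
            if (sizes < 2).any():
                raise ValueError("replicate groups must have size >= 2")

    @property
    def sample_ids(self) -> pd.Index:
        return self.age.index

    @property
    def n_samples(self) -> int:
        return len(self.age)

    def subset(self, sample_ids) -> "SurveyTable":
        ids = list(sample_ids)
        rg = None
        if self.replicate_group is not None:
            rg = self.replicate_group.loc[ids]
            # drop groups broken by subsetting (singletons are not replicates)
            sizes = rg.dropna().value_counts()
            rg = rg.where(rg.map(sizes).fillna(0) >= 2)
        return SurveyTable(
            age=self.age.loc[ids],
            lifestyle=self.lifestyle.loc[ids] if len(self.lifestyle) else self.lifestyle,
            demographics=self.demographics.loc[ids] if len(self.demographics) else self.demographics,
            categorical=self.categorical.loc[ids] if len(self.categorical) else self.categorical,
            technical=self.technical.loc[ids] if len(self.technical) else self.technical,
            replicate_group=rg,
        )


class ClusterMap:
    """Disjoint assignment of probes to clusters (cluster id -> probe ids).

    Cluster sizes may range from 1 upward; clusters are pairwise disjoint and
    non-empty.  Iteration order follows insertion order of cluster ids.
    """

    def __init__(self, clusters: dict[str, list[str]]):
        seen: set[str] = set()
        for cid, probes in clusters.items():
            if len(probes) == 0:
                raise ValueError(f"cluster {cid!r} is empty")
            pset = set(probes)
            if len(pset) != len(probes):
                raise ValueError(f"cluster {cid!r} lists a probe twice")
            overlap = seen & pset
            if overlap:
                raise ValueError(f"probe(s) {sorted(overlap)[:3]} appear in multiple clusters")
            seen |= pset
        self._clusters = {cid: list(probes) for cid, probes in clusters.items()}

    @property
    def cluster_ids(self) -> list[str]:
        return list(self._clusters)

    def members(self, cluster_id: str) -> list[str]:
        return list(self._clusters[cluster_id])

    def all_probes(self) -> list[str]:
        return [p for probes in self._clusters.values() for p in probes]

    def sizes(self) -> pd.Series:
        return pd.Series({cid: len(p) for cid, p in self._clusters.items()}, dtype=int)

    def items(self):
        return self._clusters.items()

    def subset(self, cluster_ids) -> "ClusterMap":
        return ClusterMap({cid: self._clusters[cid] for cid in cluster_ids})

    def to_dict(self) -> dict[str, list[str]]:
        return {cid: list(p) for cid, p in self._clusters.items()}

    def __len__(self) -> int:
        return len(self._clusters)

    def __iter__(self):
        return iter(self._clusters)

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self._clusters

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterMap) and self._clusters == other._clusters

    def __repr__(self) -> str:
        return f"ClusterMap({len(self)} clusters, {sum(len(p) for p in self._clusters.values())} probes)"
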