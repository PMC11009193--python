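"""Profile-based CpG clustering and cluster-average model inputs.

Probes are clustered by the similarity of their methylation profile across
the whole cohort (correlation distance, average linkage), the top clusters
are selected, and member M values are averaged per cluster to form the
independent variables for clock training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import ClusterMap, MethylationMatrix

__all__ = ["ClusterMatrix", "cluster_cpgs", "select_top_clusters", "average_clusters"]


@dataclass
class ClusterMatrix:
    """Cluster-averaged M values: one row per cluster, one column per sample."""

    values: pd.DataFrame
    cluster_map: ClusterMap

    @property
    def cluster_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_clusters(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, sample_ids) -> "ClusterMatrix":
        return ClusterMatrix(self.values[list(sample_ids)], self.cluster_map)


def cluster_cpgs(
    matrix: MethylationMatrix,
    corr_threshold: float = 0.7,
    method: str = "average",
) -> ClusterMap:
    """Cluster probes by profile similarity across the cohort.

    Hierarchical agglomerative clustering with distance ``1 - Pearson r``
    between probe profiles and the given linkage (default average), cut so
    that clusters are merged while linkage distance stays below
    ``1 - corr_threshold``.  Singletons are permitted.

    Raises if any probe has zero variance (correlation undefined) — such
    probes must be removed by upstream filtering.
    """
    if matrix.scale != "m":
        raise ValueError("cluster_cpgs expects an M-scale matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to correlate profiles")
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must be in (0, 1)")
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values must be handled before clustering")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = matrix.probe_ids[sd == 0].tolist()
        raise ValueError(f"zero-variance probes (filter upstream): {bad[:5]}")

    probe_ids = list(matrix.probe_ids)
    if len(probe_ids) == 1:
        return ClusterMap({"cl0000": probe_ids})
    dist = pdist(vals, metric="correlation")
    tree = linkage(dist, method=method)
    labels = fcluster(tree, t=1.0 - corr_threshold, criterion="distance")

    # deterministic ids ordered by first probe appearance
    order: dict[int, str] = {}
    clusters: dict[str, list[str]] = {}
    for pid, lab in zip(probe_ids, labels):
        if lab not in order:
            order[lab] = f"cl{len(order):04d}"
            clusters[order[lab]] = []
        clusters[order[lab]].append(pid)
    return ClusterMap(clusters)


def select_top_clusters(
    cmap: ClusterMap, matrix: MethylationMatrix, k: int = 10000
) -> ClusterMap:
    """Keep the top-``k`` clusters.

    Ranking: cluster size descending, ties broken by mean within-cluster probe
    variance descending, then lexicographic cluster id.  Larger clusters are
    preferred because averaging more probes suppresses measurement noise.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(cmap):
        raise ValueError(f"k={k} exceeds the {len(cmap)} available clusters")
    var = matrix.values.var(axis=1, ddof=1)

    def _key(cid: str):
        members = cmap.members(cid)
        return (-len(members), -float(var.loc[members].mean()), cid)

    ranked = sorted(cmap.cluster_ids, key=_key)
    return cmap.subset(ranked[:k])


def average_clusters(matrix: MethylationMatrix, cmap: ClusterMap) -> ClusterMatrix:
    """Average member-probe M values per cluster, ignoring missing entries.

    A cluster whose members are all missing in a sample yields a missing
    entry.  Raises when the map references a probe absent from the matrix.
    """
    if matrix.scale != "m":
        raise ValueError("average_clusters expects an M-scale matrix")
    absent = pd.Index(cmap.all_probes()).difference(matrix.probe_ids)
    if len(absent):
        raise KeyError(f"cluster map references probes absent from matrix: "
                       f"{absent.tolist()[:5]}")
    membership = pd.Series(
        {p: cid for cid, probes in cmap.items() for p in probes}, name="cluster"
    )
    sub = matrix.values.loc[membership.index]
    means = sub.groupby(membership, sort=False).mean()  # skips NaN per cell
    means = means.loc[list(cmap.cluster_ids)]  # preserve map order
    return ClusterMatrix(means, cmap)
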