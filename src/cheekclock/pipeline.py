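"""Convenience composition of the standard preprocessing steps."""

from __future__ import annotations

import warnings

from .clustering import ClusterMatrix, average_clusters
from .datatypes import ClusterMap, MethylationMatrix, ProbeManifest
from .preprocess import FilterThresholds, filter_probes

__all__ = ["cohort_cluster_matrix"]


def cohort_cluster_matrix(
    matrix: MethylationMatrix,
    manifest: ProbeManifest | None,
    cmap: ClusterMap,
    thresholds: FilterThresholds | None = None,
) -> ClusterMatrix:
    """Filter probes, keep clusters that survive intact, average them.

    The common front half of every training run: quality-filter the probe
    matrix, drop clusters that lost members to filtering (a partially
    filtered cluster no longer averages the planted signal it represents),
    and return the cluster-averaged M-value matrix.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        filtered, _ = filter_probes(matrix, manifest, thresholds=thresholds)
    surviving = set(filtered.probe_ids)
    keep = [c for c in cmap.cluster_ids if set(cmap.members(c)) <= surviving]
    return average_clusters(filtered, cmap.subset(keep))
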