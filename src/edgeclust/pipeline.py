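"""End-to-end orchestration: registered velocities -> phenotype labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from edgeclust import cluster as _cluster
from edgeclust import features as _features

__all__ = ["ClusteringOutput", "cluster_velocities"]


@dataclass
class ClusteringOutput:
    labels: np.ndarray
    dist: np.ndarray
    acf_vectors: np.ndarray
    dp: _cluster.DensityPeakResult
    sax: _features.SaxConfig
    dc: float
    k: int
    qualities: list[_cluster.ClusterQuality] | None = None


def cluster_velocities(
    matrix: np.ndarray,
    M: int = _features.SAX_M,
    N: int = _features.SAX_N,
    max_lag: int = _features.ACF_LAGS,
    dc: float | str | None = None,
    k: int | None = None,
    k_scan: range = range(2, 11),
) -> ClusteringOutput:
    """SAX -> ACF distance -> density-peak clustering of a registered set.

    ``dc`` may be a number, a preset name, or None, in which case it is
    grid-searched for the best induced clustering quality (jointly with k
    when ``k`` is also None).  When ``k`` is None with a fixed dc, the
    cluster count comes from the consensus of the DBI / silhouette /
    Calinski-Harabasz scan over ``k_scan``.
    """
    matrix = np.asarray(matrix, dtype=float)
    sax = _features.fit_sax(matrix, M=M, N=N)
    words = _features.sax_transform_set(matrix, sax)
    acf_vecs = _features.acf_matrix(words, max_lag)
    dist = _features.acf_distance_matrix(words, max_lag)
    if isinstance(dc, str):
        dc_val = _cluster.choose_dc(dist, preset=dc)
    elif dc is None:
        dc_val, k_star = _cluster.choose_dc_by_quality(dist, k=k, ks=k_scan)
        if k is None:
            k = k_star
    else:
        dc_val = float(dc)
    dp = _cluster.density_peak(dist, dc_val)
    qualities = None
    if k is None:
        qualities = _cluster.scan_k(dist, acf_vecs, dc_val, k_scan)
        k = _cluster.select_k(qualities)
    _cluster.select_centers(dp, k=k)
    labels = _cluster.assign_labels(dp)
    return ClusteringOutput(
        labels=labels,
        dist=dist,
        acf_vectors=acf_vecs,
        dp=dp,
        sax=sax,
        dc=dc_val,
        k=int(k),
        qualities=qualities,
    )
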