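"""Density-peak clustering on dissimilarity matrices, with validation tools.

Each sample gets a local density rho (Gaussian-kernel sum over all other
samples, radius dc) and a separation delta (distance to the nearest sample of
higher density; for the global density maximum, the largest pairwise
distance).  Cluster centers are samples that score high on both — visually
the upper-right region of the rho-delta decision graph — and every other
sample inherits the label of its nearest higher-density neighbour, walking
down the density ordering.

Also provided: cluster-count criteria (Davies-Bouldin, average silhouette,
Calinski-Harabasz pseudo-F), validation views (ordered dissimilarity map,
classical MDS, t-SNE with the pipeline's parameter presets, per-sample
silhouettes), and the ablation clusterers (kNN-graph community detection and
k-means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

__all__ = [
    "DensityPeakResult",
    "ClusterQuality",
    "density_peak",
    "choose_dc",
    "choose_dc_by_quality",
    "select_k",
    "select_centers",
    "assign_labels",
    "cluster_quality",
    "scan_k",
    "validation_views",
    "community_detect",
    "kmeans_baseline",
    "DC_PRESETS",
    "TSNE_PRESETS",
]

#: dc values printed for the perturbation experiments and ablations
DC_PRESETS = {"cyd": 0.71, "ck": 0.46, "no_sax": 0.61}

#: t-SNE (initial_dim, perplexity): "acf" for ACF-vector embeddings of the
#: primary pipeline, "velocity" for denoised-velocity embeddings of the
#: drug-susceptibility analysis
TSNE_PRESETS = {"acf": (10, 20), "velocity": (30, 50)}


@dataclass
class DensityPeakResult:
    rho: np.ndarray
    delta: np.ndarray
    nneigh: np.ndarray  # index of the nearest higher-density sample (-1 for the top)
    dc: float
    dist: np.ndarray
    centers: np.ndarray | None = None
    labels: np.ndarray | None = None


@dataclass(frozen=True)
class ClusterQuality:
    k: int
    dbi: float
    silhouette_avg: float
    ch_pseudo_f: float


def _check_dist(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")
    return dist


def density_peak(dist: np.ndarray, dc: float) -> DensityPeakResult:
    """Compute rho, delta and the nearest-higher-density pointer per sample.

    rho_i = sum_{k != i} exp(-(d_ik / dc)^2); delta_i = min distance to any
    sample denser than i (rho ties broken by index: lower index counts as
    denser), and for the single densest sample delta is the maximum pairwise
    distance with nneigh = -1.
    """
    dist = _check_dist(dist)
    if dc <= 0:
        raise ValueError("dc must be positive")
    n = dist.shape[0]
    kernel = np.exp(-((dist / dc) ** 2))
    rho = kernel.sum(axis=1) - 1.0  # exclude self (diagonal contributes e^0)
    # density ordering, ties broken by index
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    nneigh = np.full(n, -1, dtype=int)
    delta[order[0]] = dist.max()
    for pos in range(1, n):
        i = order[pos]
        higher = order[:pos]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        nneigh[i] = j
    return DensityPeakResult(rho=rho, delta=delta, nneigh=nneigh, dc=float(dc), dist=dist)


def choose_dc(
    dist: np.ndarray,
    target_neighbor_fraction: float = 0.02,
    preset: str | None = None,
    n_grid: int = 200,
) -> float:
    """Pick the kernel radius dc by a grid search over the distance range.

    Candidates are quantiles of the off-diagonal distances; the returned dc
    is the one whose mean Gaussian-kernel neighbourhood mass (fraction of the
    other n-1 samples) is closest to ``target_neighbor_fraction``.  The
    presets return the radii used for the perturbation experiments.
    """
    if preset is not None:
        return DC_PRESETS[preset]
    dist = _check_dist(dist)
    n = dist.shape[0]
    off = dist[~np.eye(n, dtype=bool)]
    if off.max() == 0:
        raise ValueError("all distances are zero; dc undefined")
    qs = np.linspace(0.001, 0.5, n_grid)
    candidates = np.unique(np.quantile(off[off > 0], qs))
    best_dc, best_gap = candidates[0], np.inf
    for dc in candidates:
        mass = (np.exp(-((dist / dc) ** 2)).sum(axis=1) - 1.0) / (n - 1)
        gap = abs(mass.mean() - target_neighbor_fraction)
        if gap < best_gap:
            best_dc, best_gap = dc, gap
    return float(best_dc)


def choose_dc_by_quality(
    dist: np.ndarray,
    k: int | None = None,
    ks: range | list[int] = range(2, 11),
    n_grid: int = 40,
) -> tuple[float, int]:
    """Grid-search dc (and k when free) for the best-quality decision graph.

    Candidates are log-spaced over the scale range of the positive distances
    (the distribution is lumpy when clusters are tight, so a geometric grid
    covers the between- and within-cluster scales that distance quantiles
    miss).  Each (dc, k) candidate is scored by the average silhouette of the
    induced labeling on the metric (square-root) scale of the dissimilarity;
    the best-scoring pair is returned.  Scale-equivariant: scaling all
    distances by c scales the chosen dc by c.
    """
    dist = _check_dist(dist)
    off = dist[~np.eye(dist.shape[0], dtype=bool)]
    pos = off[off > 0]
    if pos.size == 0:
        raise ValueError("all distances are zero; dc undefined")
    lo = max(np.quantile(pos, 0.01) / 2, 1e-4 * pos.max())
    grid = np.geomspace(lo, pos.max(), n_grid)
    metric_dist = np.sqrt(dist)
    k_candidates = [k] if k is not None else list(ks)
    best = (-2.0, float(grid[0]), k_candidates[0])
    for dc in grid:
        dp = density_peak(dist, dc)
        for kk in k_candidates:
            select_centers(dp, k=kk)
            labels = assign_labels(dp)
            if len(np.unique(labels)) < 2:
                continue
            score = float(np.mean(silhouette_samples(metric_dist, labels, metric="precomputed")))
            if score > best[0]:
                best = (score, float(dc), int(kk))
    return best[1], best[2]


def select_k(qualities: list["ClusterQuality"]) -> int:
    """Consensus cluster count from the three criteria.

    Majority vote among argmin DBI, argmax average silhouette and argmax
    Calinski-Harabasz; with three distinct votes the silhouette's choice
    wins (it is computed on the pipeline's native dissimilarity).
    """
    if not qualities:
        raise ValueError("no qualities to select from")
    k_dbi = min(qualities, key=lambda q: q.dbi).k
    k_sil = max(qualities, key=lambda q: q.silhouette_avg).k
    k_ch = max(qualities, key=lambda q: q.ch_pseudo_f).k
    votes = [k_dbi, k_sil, k_ch]
    for k in votes:
        if votes.count(k) >= 2:
            return k
    return k_sil


def select_centers(
    result: DensityPeakResult,
    k: int | None = None,
    manual: list[int] | None = None,
) -> np.ndarray:
    """Choose cluster centers from the decision graph.

    Automatic mode ranks samples by gamma = rho_norm * delta_norm (each
    min-max normalized) and takes the top k; manual mode accepts explicit
    sample indices picked by inspecting the rho-delta graph.
    """
    if manual is not None:
        centers = np.asarray(manual, dtype=int)
        if len(np.unique(centers)) != len(centers):
            raise ValueError("duplicate manual center indices")
        result.centers = centers
        return centers
    if k is None or k < 1 or k > len(result.rho):
        raise ValueError("k must be between 1 and the sample count")

    def _norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        # a constant factor carries no ranking information: drop it from gamma
        return np.ones_like(x) if span == 0 else (x - x.min()) / span

    gamma = _norm(result.rho) * _norm(result.delta)
    order = np.lexsort((np.arange(len(gamma)), -gamma))
    centers = np.sort(order[:k])
    result.centers = centers
    return centers


def assign_labels(result: DensityPeakResult) -> np.ndarray:
    """Propagate center labels down the density ordering via nneigh pointers.

    Labels are 1..K; centers are numbered in decreasing density order.  Every
    non-center inherits its nearest higher-density neighbour's label, which is
    already assigned when the sample is visited.
    """
    if result.centers is None:
        raise ValueError("select_centers must be called first")
    n = len(result.rho)
    order = np.lexsort((np.arange(n), -result.rho))
    labels = np.zeros(n, dtype=int)
    center_rank = {int(c): r + 1 for r, c in enumerate(sorted(result.centers, key=lambda c: -result.rho[c]))}
    for i in order:
        if i in center_rank:
            labels[i] = center_rank[i]
        else:
            j = result.nneigh[i]
            if j < 0 or labels[j] == 0:
                raise AssertionError("non-center sample has no labeled denser neighbour")
            labels[i] = labels[j]
    result.labels = labels
    return labels


def cluster_quality(
    labels: np.ndarray,
    dist: np.ndarray | None = None,
    features: np.ndarray | None = None,
) -> ClusterQuality:
    """DBI, average silhouette and Calinski-Harabasz pseudo-F for one labeling.

    The silhouette uses the precomputed dissimilarity when given (the native
    input of the pipeline), DBI/CH use the feature vectors; singleton-cluster
    silhouettes are 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for quality indices")
    if dist is None and features is None:
        raise ValueError("provide a distance matrix and/or feature vectors")
    if dist is not None:
        sil = float(np.mean(silhouette_samples(dist, labels, metric="precomputed")))
    else:
        sil = float(np.mean(silhouette_samples(features, labels)))
    if features is not None:
        dbi = float(davies_bouldin_score(features, labels))
        ch = float(calinski_harabasz_score(features, labels))
    else:
        dbi, ch = float("nan"), float("nan")
    return ClusterQuality(k=len(uniq), dbi=dbi, silhouette_avg=sil, ch_pseudo_f=ch)


def scan_k(
    dist: np.ndarray,
    features: np.ndarray | None,
    dc: float,
    ks: range | list[int] = range(2, 11),
) -> list[ClusterQuality]:
    """Cluster at each k and report the three cluster-count criteria."""
    result = density_peak(dist, dc)
    out = []
    for k in ks:
        select_centers(result, k=k)
        labels = assign_labels(result)
        if len(np.unique(labels)) < 2:
            continue
        out.append(cluster_quality(labels, dist=dist, features=features))
    return out


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS from a distance matrix via double centering."""
    dist = _check_dist(dist)
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def validation_views(
    dist: np.ndarray,
    labels: np.ndarray,
    features: np.ndarray | None = None,
    tsne_preset: str = "acf",
    seed: int = 0,
) -> dict:
    """Ordered dissimilarity map, MDS/t-SNE embeddings, per-sample silhouettes.

    The ODM reorders the matrix by (cluster, dissimilarity to the cluster
    medoid); t-SNE runs on the feature vectors after PCA reduction to the
    preset initial dimension with the preset perplexity.
    """
    dist = _check_dist(dist)
    labels = np.asarray(labels)
    n = dist.shape[0]
    order: list[int] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        medoid = members[np.argmin(dist[np.ix_(members, members)].sum(axis=1))]
        order.extend(members[np.argsort(dist[members, medoid])])
    order = np.asarray(order)
    odm = dist[np.ix_(order, order)]
    sil = silhouette_samples(dist, labels, metric="precomputed")
    mds = classical_mds(dist, 2)
    views = {"order": order, "ordered_dissimilarity_map": odm, "mds_2d": mds, "silhouette_values": sil}
    if features is not None:
        initial_dim, perplexity = TSNE_PRESETS[tsne_preset]
        if perplexity >= n / 3:
            raise ValueError("perplexity too large for the sample count")
        X = np.asarray(features, dtype=float)
        if X.shape[1] > initial_dim:
            X = PCA(n_components=initial_dim, random_state=seed).fit_transform(X)
        views["tsne_2d"] = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
    return views


def knn_graph(dist: np.ndarray, n_neighbors: int) -> nx.Graph:
    """Undirected k-nearest-neighbour graph from a dissimilarity matrix."""
    dist = _check_dist(dist)
    n = dist.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the sample count")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        # ties broken by index via stable argsort; skip self at position 0
        neighbors = np.argsort(dist[i], kind="stable")
        neighbors = neighbors[neighbors != i][:n_neighbors]
        for j in neighbors:
            g.add_edge(i, int(j))
    return g


def community_detect(dist: np.ndarray, n_neighbors: int, seed: int = 0) -> np.ndarray:
    """Modularity-maximizing (Louvain) communities on the kNN graph."""
    g = knn_graph(dist, n_neighbors)
    communities = nx.community.louvain_communities(g, seed=seed)
    labels = np.zeros(dist.shape[0], dtype=int)
    # deterministic numbering: communities ordered by their smallest member
    for lab, comm in enumerate(sorted(communities, key=min), start=1):
        for i in comm:
            labels[i] = lab
    return labels


def kmeans_baseline(series: np.ndarray, k: int = 7, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means ablation on the series themselves, best of n_init seeds by inertia."""
    series = np.asarray(series, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > series.shape[0]:
        raise ValueError("k exceeds the sample count")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(series)
    return km.labels_ + 1
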