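"""Resampling-based consensus clustering with a reduced optimal-k vote.

Samples are repeatedly subsampled and clustered with a base algorithm
(Ward hierarchical or k-means); the consensus matrix records how often two
samples land in the same cluster among the resamples where both were drawn.
Final labels come from average-linkage clustering of 1 − consensus. The
number of clusters is chosen by a majority vote of three indices: the
consensus-CDF delta-area elbow, mean silhouette and Calinski–Harabasz,
with ties broken toward smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .matrix import as_frame

BASE_METHODS = ("hierarchical-ward", "k-means")


@dataclass
class ClusterResult:
    """Output of one consensus-clustering run at a fixed k."""

    k: int
    labels: pd.Series                 # per-sample cluster index (1..k)
    consensus: np.ndarray             # n×n, symmetric, diag 1
    leaf_order: np.ndarray            # dendrogram leaf permutation of samples
    indices: dict = field(default_factory=dict)  # per-k diagnostics
    never_cosampled: int = 0


def _base_cluster(x: np.ndarray, k: int, method: str, rng) -> np.ndarray:
    """Cluster columns-as-rows matrix ``x`` (n_samples × n_features) into k."""
    if method == "hierarchical-ward":
        link = hierarchy.linkage(x, method="ward")
        return hierarchy.fcluster(link, t=k, criterion="maxclust")
    if method == "k-means":
        km = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        return km.fit_predict(x) + 1
    raise ValueError(f"unknown base method {method!r}; expected one of {BASE_METHODS}")


def consensus_cluster(matrix, k: int, n_resamples: int = 250,
                      subsample_frac: float = 0.8,
                      base_method: str = "hierarchical-ward",
                      seed: int = 0) -> ClusterResult:
    """Monti-style consensus clustering of the samples (columns) of ``matrix``."""
    frame = as_frame(matrix)
    x = frame.to_numpy(dtype=float).T  # samples × features
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = max(k, int(round(subsample_frac * n)))

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        lab = _base_cluster(x[idx], k, base_method, rng)
        ind = np.zeros((n,), dtype=int)
        ind[idx] = lab
        present = np.zeros(n, dtype=bool)
        present[idx] = True
        co_sample += np.outer(present, present)
        same = (ind[:, None] == ind[None, :]) & np.outer(present, present)
        co_cluster += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / co_sample, 0.0)
    never = int(((co_sample == 0) & ~np.eye(n, dtype=bool)).sum() // 2)
    if never:
        warnings.warn(f"{never} sample pair(s) never co-sampled; consensus set to 0")
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    # final labels: average linkage on 1 − consensus
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(link)

    indices = {"delta_area_cdf": _cdf_area(consensus)}
    if 1 < k < n and len(np.unique(labels)) > 1:
        indices["silhouette"] = float(silhouette_score(x, labels))
        indices["calinski_harabasz"] = float(calinski_harabasz_score(x, labels))
    else:
        indices["silhouette"] = np.nan
        indices["calinski_harabasz"] = np.nan

    return ClusterResult(
        k=k,
        labels=pd.Series(labels, index=frame.columns, name="cluster"),
        consensus=consensus,
        leaf_order=leaf_order,
        indices=indices,
        never_cosampled=never,
    )


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = consensus.shape[0]
    iu = np.triu_indices(n, 1)
    vals = np.sort(consensus[iu])
    if len(vals) == 0:
        return 0.0
    # A = ∫0^1 CDF(x) dx evaluated over the step function
    grid = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], np.arange(1, len(vals) + 1) / len(vals), [1.0]])
    return float(np.sum(cdf[:-1] * np.diff(grid)))


def optimal_k(results: dict[int, ClusterResult]) -> int:
    """Majority vote of three indices over the supplied k range.

    Proposals: (1) consensus-CDF delta-area elbow — the largest k whose
    relative area increase still exceeds 5%; (2) k maximizing the mean
    silhouette; (3) k maximizing Calinski–Harabasz. Majority wins; with a
    three-way disagreement the smallest proposed k is returned.
    """
    ks = sorted(results)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"results must cover a contiguous k range, got {ks}")
    areas = np.array([results[k].indices["delta_area_cdf"] for k in ks])
    k_delta = ks[0]
    for i in range(1, len(ks)):
        prev = areas[i - 1]
        rel = (areas[i] - prev) / prev if prev > 0 else np.inf
        if rel > 0.05:
            k_delta = ks[i]
    sil = [results[k].indices.get("silhouette", np.nan) for k in ks]
    ch = [results[k].indices.get("calinski_harabasz", np.nan) for k in ks]
    k_sil = ks[int(np.nanargmax(sil))]
    k_ch = ks[int(np.nanargmax(ch))]
    proposals = [k_delta, k_sil, k_ch]
    counts = pd.Series(proposals).value_counts()
    if counts.iloc[0] >= 2:
        winners = counts[counts == counts.iloc[0]].index
        return int(min(winners))
    return int(min(proposals))


def cluster_k_range(matrix, k_min: int = 2, k_max: int = 6,
                    **kwargs) -> dict[int, ClusterResult]:
    """Run :func:`consensus_cluster` for every k in ``[k_min, k_max]``."""
    return {k: consensus_cluster(matrix, k, **kwargs)
            for k in range(k_min, k_max + 1)}
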