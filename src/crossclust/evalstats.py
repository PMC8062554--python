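"""Statistics comparing single- vs cross-platform clusterings and
quantifying platform mixing within clusters.

Four families of measures, used downstream to rank data-processing
combinations:

1. agreement between single- and cross-platform clusterings: purity and
   information-theoretic comparisons (AMI, ARI, NID, NVI);
2. platform mixing: normalized platform entropy and Cramér's V of the
   cluster × platform table;
3. platform randomness inside clusters along the dendrogram leaf order:
   runs ratio and the Bartels rank version of von Neumann's ratio;
4. min(O/E): the smallest cluster relative to its balanced expectation,
   a flag for spurious clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, entropy as shannon_entropy, rankdata
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             mutual_info_score)
from sklearn.metrics.cluster import contingency_matrix


@dataclass
class EvalRecord:
    """Full statistic vector for one data-processing combination."""

    purity: float
    entropy: float
    cramers_v: float
    runs_ratio: float
    bartels_rvn: float
    ami: float
    ari: float
    nid: float
    nvi: float
    min_oe: float
    n_clusters: int

    def as_dict(self) -> dict:
        return asdict(self)

    STAT_NAMES = ("purity", "entropy", "cramers_v", "runs_ratio", "bartels_rvn",
                  "ami", "ari", "nid", "nvi", "min_oe")


def _purity_one(cross: np.ndarray, single: np.ndarray) -> float:
    table = contingency_matrix(cross, single)
    return float(table.max(axis=1).sum() / table.sum())


def purity(cross_labels: pd.Series, single_labels_by_platform: dict,
           platform_of: pd.Series) -> float:
    """Worst-case per-platform agreement of the cross-platform clustering.

    For each platform, the cross-platform labels restricted to that
    platform's samples are compared with the platform's own clustering via
    classical purity (sum over clusters of the dominant overlap, divided by
    the platform's sample count); the minimum over platforms is returned.
    """
    cross = pd.Series(cross_labels)
    plat = pd.Series(platform_of)
    vals = []
    for p, single in single_labels_by_platform.items():
        members = plat.index[plat == p]
        if len(members) == 0:
            raise ValueError(f"platform {p!r} has no samples")
        single = pd.Series(single)
        vals.append(_purity_one(cross.loc[members].to_numpy(),
                                single.loc[members].to_numpy()))
    return float(min(vals))


def platform_entropy(cluster_labels, platform_of) -> float:
    """Normalized entropy of platform composition within clusters.

    ``E = −(1/(n log2 P)) Σ_k Σ_p n_kp log2(n_kp / n_k)``; 1 when every
    cluster mixes the platforms in equal proportion, 0 when every cluster
    is single-platform.
    """
    labels = np.asarray(cluster_labels)
    plat = np.asarray(platform_of)
    platforms = np.unique(plat)
    if len(platforms) < 2:
        raise ValueError("platform entropy needs at least 2 platforms")
    n = len(labels)
    total = 0.0
    for k in np.unique(labels):
        in_k = plat[labels == k]
        n_k = len(in_k)
        for p in platforms:
            n_kp = (in_k == p).sum()
            if n_kp > 0:
                total += n_kp * np.log2(n_kp / n_k)
    return float(-total / (n * np.log2(len(platforms))) + 0.0)


def cramers_v(cluster_labels, platform_of) -> float:
    """Cramér's V of the cluster × platform contingency table."""
    table = contingency_matrix(np.asarray(cluster_labels), np.asarray(platform_of))
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if min(r, c) < 2:
        warnings.warn("degenerate contingency table; Cramér's V = 0")
        return 0.0
    chi2 = chi2_contingency(table, correction=False)[0]
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def _count_runs(seq: np.ndarray) -> int:
    if len(seq) == 0:
        return 0
    return int(1 + (seq[1:] != seq[:-1]).sum())


def runs_ratio(platform_of: pd.Series, leaf_order: np.ndarray,
               cluster_labels: pd.Series) -> float:
    """Total number of platform runs within clusters divided by n.

    Samples inside each cluster are arranged in dendrogram leaf order; the
    runs of the resulting platform-label sequences are pooled over clusters
    (size-weighted by construction) and divided by the total sample count.
    Values near 1 mean the platforms alternate (are well mixed); small
    values mean platform blocks.
    """
    plat = pd.Series(platform_of)
    labels = pd.Series(cluster_labels)
    ordered = plat.index[np.asarray(leaf_order)]
    n = len(plat)
    total_runs = 0
    for k in labels.unique():
        members = [s for s in ordered if labels.loc[s] == k]
        if len(members) == 0:
            warnings.warn(f"cluster {k} empty; skipped")
            continue
        total_runs += _count_runs(plat.loc[members].to_numpy())
    return float(total_runs / n)


def bartels_rvn(platform_of: pd.Series, leaf_order: np.ndarray,
                cluster_labels: pd.Series, min_size: int = 3) -> float:
    """Bartels rank version of von Neumann's ratio, pooled over clusters.

    Within each cluster (leaf order), the platform indicator's midranks
    R_i give ``RVN = Σ(R_i − R_{i+1})² / Σ(R_i − R̄)²``, with expectation 2
    under exchangeability; values below 2 indicate clumping, above 2 rigid
    alternation. Clusters smaller than ``min_size`` or containing a single
    platform are skipped; the size-weighted mean over the rest is returned.
    """
    plat = pd.Series(platform_of)
    labels = pd.Series(cluster_labels)
    ordered = plat.index[np.asarray(leaf_order)]
    stats, weights = [], []
    for k in labels.unique():
        members = [s for s in ordered if labels.loc[s] == k]
        if len(members) < min_size:
            continue
        seq = plat.loc[members].to_numpy()
        codes = pd.factorize(seq)[0].astype(float)
        if len(np.unique(codes)) < 2:
            warnings.warn(f"cluster {k} is single-platform; skipped in RVN")
            continue
        ranks = rankdata(codes)  # midranks for ties
        num = np.sum(np.diff(ranks) ** 2)
        den = np.sum((ranks - ranks.mean()) ** 2)
        if den == 0:
            continue
        stats.append(num / den)
        weights.append(len(members))
    if not stats:
        # every cluster platform-pure or tiny: maximal clumping
        warnings.warn("no cluster eligible for the Bartels rank statistic; "
                      "returning 0 (maximal clumping)")
        return 0.0
    return float(np.average(stats, weights=weights))


def rvn_of_sequence(values) -> float:
    """Bartels RVN of a single sequence (midranks for ties)."""
    ranks = rankdata(np.asarray(values, dtype=float))
    num = np.sum(np.diff(ranks) ** 2)
    den = np.sum((ranks - ranks.mean()) ** 2)
    if den == 0:
        raise ValueError("all values tied")
    return float(num / den)


def clustering_comparison(labels_a, labels_b) -> dict:
    """ARI, AMI, NID and NVI between two partitions of the same samples.

    NID = 1 − MI/max(H_a, H_b); NVI = 1 − MI/H_ab (joint entropy).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions cover different sample sets")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    mi = mutual_info_score(a, b)  # natural log units
    _, ca = np.unique(a, return_counts=True)
    _, cb = np.unique(b, return_counts=True)
    h_a = shannon_entropy(ca / len(a))
    h_b = shannon_entropy(cb / len(b))
    joint = contingency_matrix(a, b).ravel()
    joint = joint[joint > 0] / len(a)
    h_ab = shannon_entropy(joint)
    h_max = max(h_a, h_b)
    nid = 1.0 - mi / h_max if h_max > 0 else 0.0
    nvi = 1.0 - mi / h_ab if h_ab > 0 else 0.0
    return {
        "ari": float(adjusted_rand_score(a, b)),
        "ami": float(adjusted_mutual_info_score(a, b)),
        "nid": float(nid),
        "nvi": float(nvi),
    }


def min_oe(cluster_labels, k: int | None = None) -> float:
    """Smallest cluster size over the balanced expectation n/k."""
    labels = np.asarray(cluster_labels)
    if len(labels) == 0:
        raise ValueError("empty clustering")
    _, counts = np.unique(labels, return_counts=True)
    if k is None:
        k = len(counts)
    return float(counts.min() / (len(labels) / k))


def evaluate_clustering(cross_result, single_results: dict,
                        platform_of: pd.Series) -> EvalRecord:
    """Assemble the full :class:`EvalRecord` for one pipeline run.

    ``cross_result`` is the cross-platform :class:`ClusterResult`;
    ``single_results`` maps platform name → that platform's own
    ClusterResult. Group-1 comparison statistics are aggregated across
    platforms conservatively (min for similarities, max for distances),
    matching the worst-case purity aggregation.
    """
    cross_labels = cross_result.labels
    plat = pd.Series(platform_of)
    single_labels = {p: r.labels for p, r in single_results.items()}
    pur = purity(cross_labels, single_labels, plat)
    comps = []
    for p, lab in single_labels.items():
        members = plat.index[plat == p]
        comps.append(clustering_comparison(cross_labels.loc[members].to_numpy(),
                                           pd.Series(lab).loc[members].to_numpy()))
    rec = EvalRecord(
        purity=pur,
        entropy=platform_entropy(cross_labels.to_numpy(),
                                 plat.loc[cross_labels.index].to_numpy()),
        cramers_v=cramers_v(cross_labels.to_numpy(),
                            plat.loc[cross_labels.index].to_numpy()),
        runs_ratio=runs_ratio(plat.loc[cross_labels.index], cross_result.leaf_order,
                              cross_labels),
        bartels_rvn=bartels_rvn(plat.loc[cross_labels.index], cross_result.leaf_order,
                                cross_labels),
        ami=min(c["ami"] for c in comps),
        ari=min(c["ari"] for c in comps),
        nid=max(c["nid"] for c in comps),
        nvi=max(c["nvi"] for c in comps),
        min_oe=min_oe(cross_labels.to_numpy(), cross_result.k),
        n_clusters=int(cross_labels.nunique()),
    )
    return rec
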