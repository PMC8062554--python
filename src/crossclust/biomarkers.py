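"""Cross-platform biomarker panels for one-against-one class comparisons.

For a pair of classes, candidate genes are scored on every platform
(microarray, RNA-seq, optionally proteomics) by two criteria: large
|log2 fold change| between the classes and small overlap (OVL) of the two
classes' locally adaptive kernel densities. Panels contain the top genes
by the platform-averaged mean of the two criterion ranks, restricted to
genes whose fold-change direction agrees on every platform — a biomarker
meant to work on both transcript and protein measurements must at least
agree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .ensemble import ovl_coefficient
from .matrix import ExprMatrix, as_frame
from .units import scale_to_reference


@dataclass
class BiomarkerPanel:
    """Ordered biomarker gene set for one class pair."""

    pair: tuple[str, str]
    genes: list[str]
    table: pd.DataFrame  # per gene: log2FC and OVL per platform, combined rank
    n: int


def harmonize_platforms(expr_ma, expr_rs, protein=None, reference=None):
    """Stack platforms on their common genes after per-gene scaling.

    Every non-reference matrix is scaled gene-wise (mean and variance) to
    the reference (microarray by default) and the matrices are
    column-stacked on the genes present everywhere; genes missing from the
    protein layer are dropped and reported.

    Returns ``(stacked ExprMatrix, platform_of Series, dropped gene list)``.
    """
    ma = as_frame(reference) if reference is not None else as_frame(expr_ma)
    parts = {"microarray": as_frame(expr_ma), "rnaseq": as_frame(expr_rs)}
    if protein is not None:
        parts["protein"] = as_frame(protein)
    common = ma.index
    for frame in parts.values():
        common = common.intersection(frame.index)
    if len(common) == 0:
        raise ValueError("no gene shared by all platforms")
    dropped = ma.index.difference(common).tolist()

    stacked, plat = [], []
    for name, frame in parts.items():
        sub = frame.loc[common]
        if name != "microarray":
            sub = scale_to_reference(sub, ma.loc[common]).data
        stacked.append(sub)
        plat += [name] * sub.shape[1]
    merged = pd.concat(stacked, axis=1)
    platform_of = pd.Series(plat, index=merged.columns, name="platform")
    return (ExprMatrix(merged, unit="log2_normalized"), platform_of, dropped)


def select_biomarkers(stacked, labels: pd.Series, pair: tuple[str, str],
                      platform_of: pd.Series, n: int = 10,
                      mode: str = "rank_mean") -> BiomarkerPanel:
    """Pick the ``n`` best cross-platform discriminators for ``pair``.

    ``mode="rank_mean"`` (default) averages, over platforms, the mean of
    the |log2FC|-descending and OVL-ascending ranks; ``mode="ovl_then_fc"``
    keeps the half of genes with smallest mean OVL and sorts them by mean
    |log2FC|. Only genes whose log2FC sign agrees on every platform are
    eligible.
    """
    frame = as_frame(stacked)
    labels = pd.Series(labels)
    plat = pd.Series(platform_of)
    a, b = pair
    platforms = plat.unique().tolist()
    records = {}
    for p in platforms:
        cols_a = frame.columns[(plat == p) & (labels.reindex(plat.index) == a)]
        cols_b = frame.columns[(plat == p) & (labels.reindex(plat.index) == b)]
        if len(cols_a) < 5 or len(cols_b) < 5:
            raise ValueError(f"class pair {pair} needs >= 5 samples per class on "
                             f"platform {p!r}")
        xa = frame[cols_a].to_numpy(dtype=float)
        xb = frame[cols_b].to_numpy(dtype=float)
        lfc = xa.mean(axis=1) - xb.mean(axis=1)
        ovl = np.array([ovl_coefficient(xa[g], xb[g], n_grid=256)
                        for g in range(frame.shape[0])])
        records[p] = pd.DataFrame({"log2fc": lfc, "ovl": ovl}, index=frame.index)

    signs = np.column_stack([np.sign(records[p]["log2fc"]) for p in platforms])
    consistent = (np.abs(signs.sum(axis=1)) == len(platforms))

    per_platform_rank = []
    for p in platforms:
        r_fc = rankdata(-np.abs(records[p]["log2fc"]), method="average")
        r_ovl = rankdata(records[p]["ovl"], method="average")
        per_platform_rank.append((r_fc + r_ovl) / 2.0)
    combined = np.mean(per_platform_rank, axis=0)

    if mode == "rank_mean":
        score = combined.copy()
    elif mode == "ovl_then_fc":
        mean_ovl = np.mean([records[p]["ovl"] for p in platforms], axis=0)
        mean_fc = np.mean([np.abs(records[p]["log2fc"]) for p in platforms], axis=0)
        half = mean_ovl <= np.median(mean_ovl)
        score = np.where(half, -mean_fc, np.inf)
    else:
        raise ValueError("mode must be 'rank_mean' or 'ovl_then_fc'")

    score = np.where(consistent, score, np.inf)
    n_eligible = int(np.isfinite(score).sum())
    if n_eligible < n:
        raise ValueError(f"only {n_eligible} sign-consistent candidate(s) for "
                         f"pair {pair}; {n} required")
    order = np.lexsort((np.arange(len(score)), score))[:n]
    genes = frame.index[order].tolist()

    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for p in platforms:
        table[f"log2fc_{p}"] = records[p]["log2fc"].loc[genes]
        table[f"ovl_{p}"] = records[p]["ovl"].loc[genes]
    table["combined_rank"] = combined[order]
    return BiomarkerPanel(pair=(a, b), genes=genes, table=table, n=n)


def panel_cluster_check(stacked, panel: BiomarkerPanel, labels: pd.Series,
                        platform_of: pd.Series | None = None) -> float:
    """ARI between a 2-cut Ward clustering on the panel genes and the pair.

    Restricted to samples belonging to the panel's two classes; per-gene
    z-scoring within platform removes residual scale differences before
    clustering when ``platform_of`` is given.
    """
    frame = as_frame(stacked)
    labels = pd.Series(labels)
    mask = labels.reindex(frame.columns).isin(panel.pair)
    cols = frame.columns[mask]
    sub = frame.loc[panel.genes, cols]
    x = sub.to_numpy(dtype=float)
    if platform_of is not None:
        plat = pd.Series(platform_of).reindex(cols)
        for p in plat.unique():
            sel = (plat == p).to_numpy()
            block = x[:, sel]
            sd = block.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            x[:, sel] = (block - block.mean(axis=1, keepdims=True)) / sd
    link = hierarchy.linkage(x.T, method="ward")
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return float(adjusted_rand_score(labels.reindex(cols).to_numpy(), cut))
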