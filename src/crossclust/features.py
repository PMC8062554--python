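"""Expression-binned unsupervised feature selection.

Genes are divided into equal-count bins by mean expression (so that
low-expression, noise-dominated genes cannot crowd out the selection) and a
fixed number of genes is taken from every bin according to an unsupervised
variability/structure score: median absolute deviation, SVD-entropy
contribution, or the Laplacian score. Additional scorers can be registered
as plugins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, rankdata

from .matrix import as_frame


@dataclass
class FeatureSelSpec:
    """How many genes to select, from how many bins, with which scorer."""

    scorer: str = "mad"
    n_total: int = 1024
    n_bins: int = 8
    knn_k: int = 5
    kernel_width: float | None = None  # None = mean squared kNN distance

    def validate(self) -> "FeatureSelSpec":
        if self.n_total <= 0 or self.n_bins <= 0:
            raise ValueError("n_total and n_bins must be positive")
        if self.n_total % self.n_bins != 0:
            raise ValueError("n_total must be divisible by n_bins")
        if self.scorer not in SCORERS:
            raise ValueError(
                f"unknown scorer {self.scorer!r}; registered: {sorted(SCORERS)}")
        return self


def bin_genes(gene_means: pd.Series, n_bins: int) -> pd.Series:
    """Equal-count bins by rank of mean expression.

    Bin sizes differ by at most one; ties in the means are broken by stable
    input order. Bin 0 holds the lowest-expression genes.
    """
    means = pd.Series(gene_means)
    if n_bins > len(means):
        raise ValueError(f"n_bins={n_bins} exceeds number of genes {len(means)}")
    order = np.argsort(means.to_numpy(), kind="stable")
    bins = np.empty(len(means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return pd.Series(bins, index=means.index, name="bin")


def mad_score(matrix) -> pd.Series:
    """Per-gene median absolute deviation with the 1.4826 consistency factor."""
    frame = as_frame(matrix)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = median_abs_deviation(frame.to_numpy(dtype=float), axis=1, scale="normal")
    return pd.Series(vals, index=frame.index, name="mad")


def _spectral_entropy(eigvals: np.ndarray, r: int) -> float:
    """Normalized Shannon entropy of a squared-singular-value spectrum."""
    lam = np.clip(eigvals, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero matrix has no spectral entropy")
    rho = lam / total
    rho = rho[rho > 0]
    if r <= 1:
        return 0.0
    return float(-(rho * np.log(rho)).sum() / np.log(r))


def svd_entropy(matrix) -> float:
    """Dataset SVD entropy: normalized entropy of the squared singular values."""
    x = as_frame(matrix).to_numpy(dtype=float)
    s = np.linalg.svd(x, compute_uv=False)
    return _spectral_entropy(s ** 2, min(x.shape))


def svd_entropy_scores(matrix) -> pd.Series:
    """Per-gene SVD-entropy contribution ``CE_g = E(full) − E(without g)``.

    Genes whose removal lowers the entropy the most (largest CE) carry the
    most spectral structure and rank highest. Computed via a rank-one
    downdate of the sample-space Gram matrix, so the cost is one
    eigendecomposition of an S×S matrix per gene.
    """
    frame = as_frame(matrix)
    g, s_n = frame.shape
    if g < 2 or s_n < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    x = frame.to_numpy(dtype=float)
    if not np.any(x):
        raise ValueError("all-zero matrix")
    gram = x.T @ x  # S×S; eigenvalues = squared singular values
    e_full = _spectral_entropy(np.linalg.eigvalsh(gram), min(g, s_n))
    ce = np.empty(g)
    r_minus = min(g - 1, s_n)
    for i in range(g):
        gram_i = gram - np.outer(x[i], x[i])
        ce[i] = e_full - _spectral_entropy(np.linalg.eigvalsh(gram_i), r_minus)
    return pd.Series(ce, index=frame.index, name="svde")


def laplacian_scores(matrix, knn_k: int = 5, kernel_width: float | None = None,
                     graph_data=None) -> pd.Series:
    """Laplacian score of each gene on a heat-kernel kNN sample graph.

    Smaller is better: a low score means the gene varies smoothly along the
    sample manifold (respects local structure) rather than behaving like
    noise. Zero-variance genes get ``+inf`` and rank last. The graph is
    built from ``graph_data`` (default: the scored matrix itself); for a
    fixed graph the score is invariant to positive rescaling of a gene.
    """
    frame = as_frame(matrix)
    x = frame.to_numpy(dtype=float)
    g, n = x.shape
    if n <= knn_k:
        raise ValueError(f"need more than knn_k={knn_k} samples, got {n}")
    # pairwise squared distances between samples
    xg = as_frame(graph_data).to_numpy(dtype=float) if graph_data is not None else x
    sq = (xg ** 2).sum(axis=0)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (xg.T @ xg), 0.0)
    np.fill_diagonal(d2, np.inf)
    knn_idx = np.argsort(d2, axis=1, kind="stable")[:, :knn_k]
    knn_d2 = np.take_along_axis(d2, knn_idx, axis=1)
    t = float(kernel_width) if kernel_width is not None else float(knn_d2.mean())
    if t <= 0:
        t = 1.0
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), knn_k)
    adj[rows, knn_idx.ravel()] = True
    adj |= adj.T  # symmetric kNN graph
    w = np.where(adj, np.exp(-d2 / t), 0.0)
    np.fill_diagonal(w, 0.0)
    deg = w.sum(axis=1)
    dtot = deg.sum()
    scores = np.empty(g)
    for i in range(g):
        f = x[i]
        if np.ptp(f) == 0:  # zero-variance gene: rank last
            scores[i] = np.inf
            continue
        f_t = f - (f @ deg) / dtot
        denom = (f_t ** 2) @ deg
        if denom <= 1e-300:
            scores[i] = np.inf
            continue
        lap = f_t @ (deg * f_t) - f_t @ (w @ f_t)  # f'Lf with L = D − W
        scores[i] = lap / denom
    return pd.Series(scores, index=frame.index, name="lscore")


# scorer registry: name -> (function(matrix, spec) -> Series, higher_is_better)
def _mad(matrix, spec):
    return mad_score(matrix)


def _svde(matrix, spec):
    return svd_entropy_scores(matrix)


def _lscore(matrix, spec):
    return laplacian_scores(matrix, knn_k=spec.knn_k, kernel_width=spec.kernel_width)


SCORERS: dict[str, tuple[Callable, bool]] = {
    "mad": (_mad, True),
    "svde": (_svde, True),
    "lscore": (_lscore, False),
}


def register_scorer(name: str, func: Callable, higher_is_better: bool) -> None:
    """Plugin hook: register ``func(matrix, spec) -> per-gene Series``."""
    SCORERS[name] = (func, higher_is_better)


def select_features(matrix, spec: FeatureSelSpec | None = None) -> list[str]:
    """Select ``spec.n_total`` genes, equally many from each expression bin.

    Within each bin genes are ranked by the scorer (direction per scorer)
    and the top ``n_total / n_bins`` taken; the returned list is ordered by
    bin then rank, and is deterministic (stable tie-breaking by input gene
    order).
    """
    spec = (spec or FeatureSelSpec()).validate()
    frame = as_frame(matrix)
    per_bin = spec.n_total // spec.n_bins
    bins = bin_genes(frame.mean(axis=1), spec.n_bins)
    func, higher = SCORERS[spec.scorer]
    scores = pd.Series(func(frame, spec)).reindex(frame.index)
    selected: list[str] = []
    for b in range(spec.n_bins):
        members = bins.index[bins.to_numpy() == b]
        if len(members) < per_bin:
            raise ValueError(
                f"bin {b} holds {len(members)} genes but {per_bin} are required")
        vals = scores.loc[members].to_numpy(dtype=float)
        key = -vals if higher else vals
        # stable sort keeps input gene order on ties
        order = np.argsort(key, kind="stable")[:per_bin]
        selected.extend(members[order].tolist())
    return selected
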