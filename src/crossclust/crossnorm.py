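"""Cross-platform normalization of merged expression matrices.

Four methods for removing the systematic scale differences between
count-based (RNA-seq) and intensity-based (microarray) expression values:

* :func:`fsqn` — feature-specific quantile normalization: per gene, map the
  target platform's values onto the empirical quantiles of the reference
  platform, preserving each gene's center and spread on the reference scale.
* :func:`quantile_norm` — classic whole-column quantile normalization.
* :func:`tdm` — training distribution matching: clamp target tails using
  the reference's relative tail spreads (in IQR units) and map the result
  affinely into ``[min(reference), max(reference)]``.
* :func:`combat` — parametric empirical-Bayes location/scale batch
  adjustment, with the platform (or series) as the batch variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExprMatrix, as_frame

__all__ = ["fsqn", "quantile_norm", "tdm", "combat", "merge_platforms"]


def _plotting_positions(n: int) -> np.ndarray:
    return (np.arange(1, n + 1) - 0.5) / n


def fsqn(target, reference) -> ExprMatrix:
    """Feature-specific quantile normalization of ``target`` onto ``reference``.

    For each gene independently, the sorted target values are replaced by
    linearly interpolated empirical quantiles of that gene's reference
    values at plotting positions ``(k - 0.5) / n_target``; ties in the
    target are broken by stable order, so within-gene ranks are preserved.
    """
    t = as_frame(target)
    r = as_frame(reference)
    missing = t.index.difference(r.index)
    if len(missing):
        raise ValueError(f"gene(s) absent from reference: {missing.tolist()[:5]}")
    if r.shape[1] < 2:
        raise ValueError("reference must have at least 2 samples")
    r = r.loc[t.index]
    tv = t.to_numpy(dtype=float)
    rv = r.to_numpy(dtype=float)
    n_t, n_r = tv.shape[1], rv.shape[1]
    p_t = _plotting_positions(n_t)
    p_r = _plotting_positions(n_r)
    out = np.empty_like(tv)
    ref_sorted = np.sort(rv, axis=1)
    order = np.argsort(tv, axis=1, kind="stable")
    for g in range(tv.shape[0]):
        vals = np.interp(p_t, p_r, ref_sorted[g])
        out[g, order[g]] = vals
    return ExprMatrix(pd.DataFrame(out, index=t.index, columns=t.columns),
                      unit="log2_normalized")


def quantile_norm(matrix, reference=None) -> ExprMatrix:
    """Whole-column quantile normalization.

    Without a reference, each column's sorted values are replaced by the
    row-wise mean of all sorted columns; with a reference, by the
    reference's mean-quantile vector (interpolated when gene counts
    differ). Column rank orders are preserved (stable ties).
    """
    m = as_frame(matrix)
    if m.shape[1] < 2 and reference is None:
        warnings.warn("quantile_norm: fewer than 2 samples; passthrough")
        return ExprMatrix(m.copy(), unit="log2_normalized")
    if m.shape[0] < 2:
        warnings.warn("quantile_norm: single-gene matrix; passthrough")
        return ExprMatrix(m.copy(), unit="log2_normalized")
    x = m.to_numpy(dtype=float)
    g = x.shape[0]
    if reference is None:
        template = np.sort(x, axis=0).mean(axis=1)
    else:
        r = as_frame(reference).to_numpy(dtype=float)
        ref_template = np.sort(r, axis=0).mean(axis=1)
        if len(ref_template) == g:
            template = ref_template
        else:
            template = np.interp(_plotting_positions(g),
                                 _plotting_positions(len(ref_template)), ref_template)
    order = np.argsort(x, axis=0, kind="stable")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = template
    return ExprMatrix(pd.DataFrame(out, index=m.index, columns=m.columns),
                      unit="log2_normalized")


def tdm(target, reference, target_is_linear: bool | None = None) -> ExprMatrix:
    """Training distribution matching of ``target`` onto a log2 ``reference``.

    The reference's relative tail spreads above Q3 and below Q1 (in IQR
    units) bound how far the (log2) target may extend beyond its own
    quartiles; values beyond those bounds are clamped, and the clamped
    target is mapped affinely onto ``[min(reference), max(reference)]``.
    Raw-count or linear targets are log2(x+1)-transformed first; already
    logged targets are un-logged and re-logged so the entry path is the
    same. The map is monotone and the output lies inside the reference
    range.
    """
    t = as_frame(target)
    r = as_frame(reference)
    if r.size == 0:
        raise ValueError("reference is empty")
    if target_is_linear is None:
        target_is_linear = isinstance(target, ExprMatrix) and target.unit in (
            "counts", "linear")
    x = t.to_numpy(dtype=float)
    if not target_is_linear:
        # mirror the raw-entry path: back to linear, then log2(x+1)
        x = np.exp2(x)
    x = np.log2(x + 1.0)

    rv = r.to_numpy(dtype=float).ravel()
    q1_r, q3_r = np.percentile(rv, [25, 75])
    iqr_r = q3_r - q1_r
    if iqr_r <= 0:
        raise ValueError("reference IQR is zero")
    spread_hi = (rv.max() - q3_r) / iqr_r
    spread_lo = (q1_r - rv.min()) / iqr_r

    xf = x.ravel()
    q1_t, q3_t = np.percentile(xf, [25, 75])
    iqr_t = q3_t - q1_t
    if iqr_t <= 0:
        raise ValueError("target IQR is zero")
    hi = q3_t + spread_hi * iqr_t
    lo = q1_t - spread_lo * iqr_t
    clamped = np.clip(x, lo, hi)
    cmin, cmax = clamped.min(), clamped.max()
    if cmax == cmin:
        raise ValueError("target is constant after clamping")
    out = (clamped - cmin) / (cmax - cmin) * (rv.max() - rv.min()) + rv.min()
    return ExprMatrix(pd.DataFrame(out, index=t.index, columns=t.columns),
                      unit="log2_normalized")


def combat(matrix, batch_of, parametric: bool = True) -> ExprMatrix:
    """Parametric empirical-Bayes batch correction (ComBat).

    ``batch_of`` assigns each sample (column) a batch label. Per-gene batch
    location/scale parameters are shrunk toward batch-level priors and the
    data back-transformed; with a single batch the input is returned
    unchanged. Backed by scanpy's ComBat implementation; no covariates are
    used, matching how the pipeline calls it (platform — or series — as the
    sole batch variable).
    """
    if not parametric:
        raise NotImplementedError("only parametric ComBat is supported")
    m = as_frame(matrix)
    batch = pd.Series(batch_of)
    if not m.columns.isin(batch.index).all():
        batch = pd.Series(np.asarray(batch_of), index=m.columns)
    else:
        batch = batch.reindex(m.columns)
    counts = batch.value_counts()
    if len(counts) == 1:
        return ExprMatrix(m.copy(), unit="log2_normalized")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch(es) with fewer than 2 samples: {small.index.tolist()}")
    pooled_var = m.to_numpy(dtype=float).var(axis=1)
    if (pooled_var == 0).any():
        bad = m.index[pooled_var == 0].tolist()
        raise ValueError(f"zero pooled variance for gene(s): {bad[:5]}")

    import anndata as ad
    import scanpy as sc

    obs = pd.DataFrame({"batch": pd.Categorical(batch.astype(str))},
                       index=m.columns.astype(str))
    adata = ad.AnnData(X=m.to_numpy(dtype=float).T, obs=obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = sc.pp.combat(adata, key="batch", inplace=False)
    if not np.isfinite(corrected).all():
        raise RuntimeError("ComBat produced non-finite values (non-convergence)")
    return ExprMatrix(pd.DataFrame(corrected.T, index=m.index, columns=m.columns),
                      unit="log2_normalized")


def merge_platforms(ma, rs) -> tuple[ExprMatrix, pd.Series]:
    """Column-stack two platform matrices on their shared genes.

    Returns the merged matrix and a per-sample platform label series
    (reference platform = microarray).
    """
    a = as_frame(ma)
    b = as_frame(rs)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("platforms share no genes")
    merged = pd.concat([a.loc[shared], b.loc[shared]], axis=1)
    if merged.columns.has_duplicates:
        raise ValueError("duplicate sample ids across platforms")
    platform_of = pd.Series(
        ["microarray"] * a.shape[1] + ["rnaseq"] * b.shape[1],
        index=merged.columns, name="platform",
    )
    return ExprMatrix(merged, unit="log2_normalized"), platform_of
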