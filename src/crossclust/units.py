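"""Per-sample RNA-seq normalization units.

Converts raw count matrices to the normalized scales crossed in the method
grid: CPM, RPKM, FPKM (median-of-ratios size factors), shifted log,
a closed-form negative-binomial variance-stabilizing transform, and the
log-CPM used by voom. Also provides per-gene mean/variance scaling of one
matrix onto a reference, used when stacking platforms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExprMatrix, as_frame

LN2 = np.log(2.0)


def _counts_frame(counts) -> pd.DataFrame:
    frame = as_frame(counts)
    if (frame.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return frame


def _lib_sizes(frame: pd.DataFrame) -> pd.Series:
    lib = frame.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {zero.index.tolist()}")
    return lib


def _lengths_for(frame: pd.DataFrame, lengths_bp) -> np.ndarray:
    lengths = pd.Series(lengths_bp)
    missing = frame.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length(s): {missing.tolist()[:5]}")
    vals = lengths.reindex(frame.index).to_numpy(dtype=float)
    if (vals <= 0).any() or np.isnan(vals).any():
        raise ValueError("gene lengths must be positive")
    return vals


def cpm(counts, prior_count: float = 0.0, log_output: bool = False) -> ExprMatrix:
    """Counts per million: ``(c + p) / (N + 2p) * 1e6``.

    With ``log_output`` the result is log2-transformed, which requires a
    positive ``prior_count``.
    """
    frame = _counts_frame(counts)
    if log_output and prior_count <= 0:
        raise ValueError("log output requires prior_count > 0")
    lib = _lib_sizes(frame).to_numpy()
    out = (frame.to_numpy() + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6
    if log_output:
        return ExprMatrix(pd.DataFrame(np.log2(out), index=frame.index,
                                       columns=frame.columns), unit="log2_normalized")
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="linear")


def rpkm(counts, lengths_bp, prior_count: float = 0.0,
         log_output: bool = False) -> ExprMatrix:
    """Reads per kilobase per million: CPM divided by gene length in kb."""
    frame = _counts_frame(counts)
    lengths = _lengths_for(frame, lengths_bp)
    base = cpm(frame, prior_count=prior_count, log_output=False).data
    out = base.to_numpy() / (lengths / 1e3)[:, None]
    if log_output:
        if prior_count <= 0:
            raise ValueError("log output requires prior_count > 0")
        out = np.log2(out)
        return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                          unit="log2_normalized")
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="linear")


def size_factors_median_ratio(counts) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses genes with positive counts in every sample; the factor for sample
    *i* is the median over such genes of ``c_gi / geomean_j(c_gj)``.
    """
    frame = _counts_frame(counts)
    x = frame.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = x[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=frame.columns, name="size_factor")


def fpkm(counts, lengths_bp, size_factors=None) -> ExprMatrix:
    """Fragments per kilobase per million on size-factor-corrected counts.

    ``FPKM_gi = (c_gi / s_i) / ((L_g / 1e3) * (Ñ / 1e6))`` with *Ñ* the
    geometric mean of the library sizes.
    """
    frame = _counts_frame(counts)
    lengths = _lengths_for(frame, lengths_bp)
    if size_factors is None:
        size_factors = size_factors_median_ratio(frame)
    s = pd.Series(size_factors).reindex(frame.columns).to_numpy(dtype=float)
    if (s <= 0).any() or np.isnan(s).any():
        raise ValueError("size factors must be positive for every sample")
    lib = _lib_sizes(frame).to_numpy()
    n_tilde = np.exp(np.mean(np.log(lib)))
    out = (frame.to_numpy() / s[None, :]) / ((lengths / 1e3)[:, None] * (n_tilde / 1e6))
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="linear")


def shifted_log(counts, size_factors=None) -> ExprMatrix:
    """Shifted log transform ``log2(c / s + 1)``."""
    frame = _counts_frame(counts)
    if size_factors is None:
        size_factors = size_factors_median_ratio(frame)
    s = pd.Series(size_factors).reindex(frame.columns).to_numpy(dtype=float)
    if (s <= 0).any() or np.isnan(s).any():
        raise ValueError("size factors must be positive for every sample")
    out = np.log2(frame.to_numpy() / s[None, :] + 1.0)
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="log2_normalized")


def estimate_common_dispersion(counts, size_factors=None) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    For each gene with variance exceeding its mean, ``(v - m) / m²``
    estimates the dispersion; the median over genes is returned.
    """
    frame = _counts_frame(counts)
    if not (frame.to_numpy() > 0).any():
        raise ValueError("cannot estimate dispersion from an all-zero matrix")
    if size_factors is None:
        size_factors = size_factors_median_ratio(frame)
    s = pd.Series(size_factors).reindex(frame.columns).to_numpy(dtype=float)
    norm = frame.to_numpy() / s[None, :]
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    ok = (m > 0) & (v > m)
    if not ok.any():
        # Poisson-like data: fall back to a tiny dispersion
        return 1e-4
    return float(np.median((v[ok] - m[ok]) / m[ok] ** 2))


def vst_closed_form(counts, size_factors=None, dispersion="auto") -> ExprMatrix:
    """Closed-form NB variance-stabilizing transform.

    Applies ``v(x) = 2·asinh(√(α·x/s)) / ln2 − log2(4α)`` — the asinh
    stabilizer for a negative binomial with common dispersion α, affinely
    scaled so that ``v(x) → log2(x)`` for large counts. ``dispersion="auto"``
    estimates α by the method of moments on size-factor-normalized counts.
    """
    frame = _counts_frame(counts)
    if size_factors is None:
        size_factors = size_factors_median_ratio(frame)
    s = pd.Series(size_factors).reindex(frame.columns).to_numpy(dtype=float)
    if dispersion == "auto":
        alpha = estimate_common_dispersion(frame, size_factors=s)
    else:
        alpha = float(dispersion)
    if not alpha > 0:
        raise ValueError("dispersion must be positive")
    xhat = frame.to_numpy() / s[None, :]
    out = 2.0 * np.arcsinh(np.sqrt(alpha * xhat)) / LN2 - np.log2(4.0 * alpha)
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="log2_normalized")


def voom_logcpm(counts, prior_count: float = 0.5) -> ExprMatrix:
    """voom's log-CPM: ``log2((c + 0.5) / (N + 1) * 1e6)``.

    Only the log-CPM component is used here; voom's observation-level
    precision weights belong to linear-model fitting, which this pipeline
    does not perform.
    """
    frame = _counts_frame(counts)
    lib = _lib_sizes(frame).to_numpy()
    out = np.log2((frame.to_numpy() + prior_count) / (lib + 1.0)[None, :] * 1e6)
    return ExprMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns),
                      unit="log2_normalized")


def scale_to_reference(target, reference) -> ExprMatrix:
    """Per-gene mean/variance scaling of ``target`` onto ``reference``.

    For each shared gene the target row is standardized and re-expressed on
    the reference row's mean and standard deviation. Zero-variance target
    rows map to the reference mean.
    """
    t = as_frame(target)
    r = as_frame(reference)
    shared = t.index.intersection(r.index)
    if len(shared) == 0:
        raise ValueError("target and reference share no genes")
    t = t.loc[shared]
    r = r.loc[shared]
    tv = t.to_numpy(dtype=float)
    rv = r.to_numpy(dtype=float)
    t_mean = tv.mean(axis=1, keepdims=True)
    t_sd = tv.std(axis=1, ddof=1, keepdims=True)
    r_mean = rv.mean(axis=1, keepdims=True)
    r_sd = rv.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (tv - t_mean) / t_sd
    z = np.where(t_sd > 0, z, 0.0)
    out = z * r_sd + r_mean
    return ExprMatrix(pd.DataFrame(out, index=shared, columns=t.columns),
                      unit="log2_normalized")
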