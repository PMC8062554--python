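"""Synthetic two-platform cohorts with planted tumor subtypes.

The generator emulates the structure of a pooled microarray + RNA-seq lung
cohort: a latent per-gene log2 expression level shared across platforms,
subtype-specific shifts on a subset of marker genes, gene-length-dependent
negative-binomial sequencing counts, per-gene monotone platform distortion
(probe saturation) on the microarray side, within-platform batch shifts and
a small fraction of outlier samples whose gene profile is scrambled.

Every random draw flows from ``SimConfig.seed``; the same config yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExprMatrix, validate_meta

PLATFORM_EFFECTS = ("none", "affine", "monotone")


@dataclass
class SimConfig:
    """Parameters of a simulated two-platform cohort.

    Defaults give a cohort in which platform effects dominate raw merged
    data (clusters split by platform) while the planted subtype signal is
    recoverable after cross-platform normalization.
    """

    n_genes: int = 2000
    n_samples_per_platform: int = 120
    n_subtypes: int = 3
    frac_marker_genes: float = 0.10
    effect_size_log2: float = 2.0
    platform_effect: str = "monotone"  # none | affine | monotone
    batch_sd: float = 0.2
    n_batches: int = 2
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (5e5, 2e6)
    frac_outliers: float = 0.0
    include_normal: bool = False
    include_protein: bool = False
    frac_protein_genes: float = 0.3
    # latent-scale nuisance parameters
    mu_mean: float = 4.0
    mu_sd: float = 2.0
    bio_sd: float = 0.5
    array_noise_sd: float = 0.3
    protein_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise ValueError("n_genes must be a positive integer")
        if not (isinstance(self.n_samples_per_platform, (int, np.integer))
                and self.n_samples_per_platform > 0):
            raise ValueError("n_samples_per_platform must be a positive integer")
        if not (isinstance(self.n_subtypes, (int, np.integer)) and self.n_subtypes >= 1):
            raise ValueError("n_subtypes must be an integer >= 1")
        if not 0 < self.frac_marker_genes <= 1:
            raise ValueError("frac_marker_genes must lie in (0, 1]")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be nonnegative")
        if self.platform_effect not in PLATFORM_EFFECTS:
            raise ValueError(f"platform_effect must be one of {PLATFORM_EFFECTS}")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be a pair of positive reals, lo <= hi")
        if not 0 <= self.frac_outliers < 1:
            raise ValueError("frac_outliers must lie in [0, 1)")
        if not 0 < self.frac_protein_genes <= 1:
            raise ValueError("frac_protein_genes must lie in (0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        return self


@dataclass
class SimCohort:
    """A simulated cohort: one matrix per platform plus ground truth."""

    counts_rnaseq: ExprMatrix
    intensities_microarray: ExprMatrix
    protein: Optional[ExprMatrix]
    meta: pd.DataFrame          # index sample_id; platform, batch, label, subtype, outlier
    gene_anno: pd.DataFrame     # index gene_id; length_bp, marker, marker_subtype, marker_sign
    true_labels: pd.Series      # per sample planted class
    latent: pd.DataFrame        # shared-scale log2 latent expression, all samples
    config: SimConfig = field(repr=False, default=None)


def _class_names(config: SimConfig) -> list[str]:
    names = [f"S{i + 1}" for i in range(config.n_subtypes)]
    if config.include_normal:
        names.append("normal")
    return names


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw a full two-platform cohort from ``config``.

    Returns a :class:`SimCohort` whose RNA-seq matrix holds raw negative
    binomial counts, whose microarray matrix holds log2 intensities, and —
    when ``include_protein`` — a log2 protein-abundance matrix over a
    random subset of genes correlated with the latent mRNA level.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n_pp = config.n_samples_per_platform
    classes = _class_names(config)
    n_classes = len(classes)

    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id")
    lengths = np.exp(rng.normal(np.log(1500.0), 0.5, size=G))  # bp

    # marker genes: each gets one subtype (never "normal") and a sign
    n_markers = int(round(config.frac_marker_genes * G))
    marker_idx = rng.choice(G, size=n_markers, replace=False)
    marker = np.zeros(G, dtype=bool)
    marker[marker_idx] = True
    marker_subtype = np.full(G, "", dtype=object)
    marker_sign = np.zeros(G, dtype=int)
    marker_subtype[marker_idx] = rng.choice(
        [f"S{i + 1}" for i in range(config.n_subtypes)], size=n_markers
    )
    marker_sign[marker_idx] = rng.choice([-1, 1], size=n_markers)
    # per-marker effect magnitude around the configured mean
    effect = np.zeros(G)
    if config.effect_size_log2 > 0:
        effect[marker_idx] = np.abs(
            rng.normal(config.effect_size_log2, config.effect_size_log2 / 4, size=n_markers)
        )

    mu = rng.normal(config.mu_mean, config.mu_sd, size=G)

    # sample bookkeeping: balanced classes per platform
    def _labels(n: int) -> np.ndarray:
        reps = int(np.ceil(n / n_classes))
        lab = np.tile(classes, reps)[:n]
        return rng.permutation(lab)

    platforms, all_samples, labels, batches = [], [], [], []
    for plat, prefix in (("microarray", "MA"), ("rnaseq", "RS")):
        ids = [f"{prefix}{i:04d}" for i in range(n_pp)]
        all_samples += ids
        platforms += [plat] * n_pp
        labels.append(_labels(n_pp))
        batches.append(rng.integers(0, config.n_batches, size=n_pp))
    labels = np.concatenate(labels)
    batch_ids = np.concatenate(batches)
    platforms = np.array(platforms)
    samples = pd.Index(all_samples, name="sample_id")
    n_total = 2 * n_pp

    # latent log2 expression shared across platforms
    shift = np.zeros((G, n_total))
    for j, lab in enumerate(labels):
        hit = marker & (marker_subtype == lab)
        shift[hit, j] = marker_sign[hit] * effect[hit]
    latent = mu[:, None] + shift + rng.normal(0.0, config.bio_sd, size=(G, n_total))

    # per-(platform, batch, gene) shifts
    if config.batch_sd > 0:
        for plat in ("microarray", "rnaseq"):
            for b in range(config.n_batches):
                cols = (platforms == plat) & (batch_ids == b)
                if cols.any():
                    latent_shift = rng.normal(0.0, config.batch_sd, size=G)
                    latent[:, cols] += latent_shift[:, None]

    ma_cols = platforms == "microarray"
    rs_cols = platforms == "rnaseq"

    # ---- RNA-seq: NB counts, mean ∝ libsize × length × 2^latent ----------
    libsize = rng.uniform(*config.libsize_range, size=rs_cols.sum())
    weight = lengths[:, None] * np.exp2(latent[:, rs_cols])
    p = weight / weight.sum(axis=0, keepdims=True)
    mean = p * libsize[None, :]
    alpha = config.nb_dispersion  # var = m + alpha m^2
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    counts = rng.poisson(lam).astype(np.int64)

    # ---- microarray: monotone per-gene transform of the latent -----------
    x_ma = latent[:, ma_cols]
    if config.platform_effect == "none":
        y = x_ma
    elif config.platform_effect == "affine":
        a = rng.normal(0.0, 0.5, size=G)[:, None]
        b = rng.normal(1.0, 0.1, size=G)[:, None]
        y = a + b * x_ma
    else:  # monotone probe saturation on the linear scale
        L = 2.0 ** 14
        K = np.exp2(mu + 1.0)[:, None]  # per-gene half-saturation near 2x median
        lin = np.exp2(x_ma)
        y = np.log2(1.0 + L * lin / (lin + K))
    y = y + rng.normal(0.0, config.array_noise_sd, size=y.shape)

    # ---- outliers: per-gene scramble across same-platform samples --------
    # Each outlier becomes a chimera: for every gene, its value is borrowed
    # from a random other sample of the same platform. This destroys the
    # class signal while leaving every per-gene marginal distribution (the
    # quantity classifiers and normalizers see) unchanged.
    n_out = int(round(config.frac_outliers * n_total))
    outlier = np.zeros(n_total, dtype=bool)
    if n_out:
        rs_pos = {j: i for i, j in enumerate(np.flatnonzero(rs_cols))}
        ma_pos = {j: i for i, j in enumerate(np.flatnonzero(ma_cols))}
        out_idx = rng.choice(n_total, size=n_out, replace=False)
        outlier[out_idx] = True
        gene_ix = np.arange(G)
        for j in out_idx:
            if platforms[j] == "rnaseq":
                jj = rs_pos[j]
                donors = rng.integers(0, counts.shape[1], size=G)
                donors[donors == jj] = (donors[donors == jj] + 1) % counts.shape[1]
                counts[:, jj] = counts[gene_ix, donors]
            else:
                jj = ma_pos[j]
                donors = rng.integers(0, y.shape[1], size=G)
                donors[donors == jj] = (donors[donors == jj] + 1) % y.shape[1]
                y[:, jj] = y[gene_ix, donors]
            lat_donors = rng.integers(0, n_total, size=G)
            lat_donors[lat_donors == j] = (lat_donors[lat_donors == j] + 1) % n_total
            latent[:, j] = latent[gene_ix, lat_donors]

    meta = pd.DataFrame(
        {
            "platform": platforms,
            "batch": [f"{p[:2]}_b{b}" for p, b in zip(platforms, batch_ids)],
            "label": labels,
            "subtype": labels,
            "outlier": outlier,
        },
        index=samples,
    )
    validate_meta(meta)

    gene_anno = pd.DataFrame(
        {
            "length_bp": lengths,
            "marker": marker,
            "marker_subtype": marker_subtype,
            "marker_sign": marker_sign,
        },
        index=genes,
    )

    counts_rnaseq = ExprMatrix(
        pd.DataFrame(counts, index=genes, columns=samples[rs_cols]), unit="counts"
    )
    intensities = ExprMatrix(
        pd.DataFrame(y, index=genes, columns=samples[ma_cols]), unit="log2_intensity"
    )

    protein = None
    if config.include_protein:
        n_prot = int(round(config.frac_protein_genes * G))
        prot_idx = np.sort(rng.choice(G, size=n_prot, replace=False))
        base = latent[prot_idx, :]
        centered = base - base.mean(axis=1, keepdims=True)
        prot = (
            base.mean(axis=1, keepdims=True)
            + 0.8 * centered
            + rng.normal(0.0, config.protein_noise_sd, size=base.shape)
        )
        prot_samples = pd.Index([f"PR{i:04d}" for i in range(n_total)], name="sample_id")
        protein = ExprMatrix(
            pd.DataFrame(prot, index=genes[prot_idx], columns=prot_samples),
            unit="log2_normalized",
        )
        prot_meta = pd.DataFrame(
            {
                "platform": "protein",
                "batch": "pr_b0",
                "label": labels,
                "subtype": labels,
                "outlier": outlier,
            },
            index=prot_samples,
        )
        meta = pd.concat([meta, prot_meta])

    true_labels = meta["subtype"].copy()
    latent_df = pd.DataFrame(latent, index=genes, columns=samples)
    return SimCohort(
        counts_rnaseq=counts_rnaseq,
        intensities_microarray=intensities,
        protein=protein,
        meta=meta,
        gene_anno=gene_anno,
        true_labels=true_labels,
        latent=latent_df,
        config=config,
    )


def spike_mislabels(meta: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Flip the class label of ``round(fraction * n)`` samples.

    Returns a copy of ``meta`` with flipped ``label`` values and a boolean
    ``flipped`` column marking which samples were altered. The flip replaces
    the label with a different one drawn uniformly from the remaining
    classes. ``fraction`` must lie in [0, 1).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    validate_meta(meta)
    out = meta.copy()
    out["flipped"] = False
    n = len(out)
    n_flip = int(round(fraction * n))
    if n_flip == 0:
        return out
    rng = np.random.default_rng(seed)
    classes = np.array(sorted(out["label"].dropna().unique()))
    if len(classes) < 2:
        raise ValueError("need at least two classes to mislabel")
    idx = rng.choice(n, size=n_flip, replace=False)
    for j in idx:
        current = out["label"].iloc[j]
        others = classes[classes != current]
        out.iloc[j, out.columns.get_loc("label")] = rng.choice(others)
    out.iloc[idx, out.columns.get_loc("flipped")] = True
    return out
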