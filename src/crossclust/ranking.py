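"""Method-grid enumeration, filtering and rank aggregation.

The grid crosses microarray preprocessing × RNA-seq unit × cross-platform
normalizer × unsupervised feature scorer (2 × 6 × 4 × 8 = 384 cells). Each
cell is evaluated by consensus-clustering the merged data and both single
platforms and scoring the agreement/mixing statistics; combinations are
then filtered (purity, min(O/E), platform entropy) and ranked by the
equal-weight mean of four statistic-group ranks.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import crossnorm, units
from .consensus import consensus_cluster
from .evalstats import EvalRecord, evaluate_clustering
from .features import SCORERS, FeatureSelSpec, select_features
from .matrix import ExprMatrix, as_frame
from .sim import SimCohort

MA_METHODS = ("mas5", "rma")
RS_METHODS = ("cpm", "fpkm", "normTransform", "rpkm", "voom", "vst")
XNORM_METHODS = ("ComBat", "FSQN", "quantile", "TDM")
UFS_METHODS = ("disr", "lscore", "mad", "mcfs", "specu", "spufs", "svde", "udfs")

#: statistic groups for the equal-weight final ranking
STAT_GROUPS = (
    ("purity", "ami", "ari", "nid", "nvi"),
    ("entropy", "cramers_v"),
    ("runs_ratio", "bartels_rvn"),
    ("min_oe",),
)
#: ranking direction: True = higher is better
HIGHER_BETTER = {
    "purity": True, "ami": True, "ari": True, "nid": False, "nvi": False,
    "entropy": True, "cramers_v": False, "runs_ratio": True, "min_oe": True,
    # bartels_rvn handled separately: ranked by ascending |RVN − 2|
}


@dataclass(frozen=True, order=True)
class CombinationSpec:
    """One cell of the data-processing method grid."""

    ma_method: str
    rs_method: str
    xnorm: str
    ufs: str

    def validate(self) -> "CombinationSpec":
        for value, pool, name in ((self.ma_method, MA_METHODS, "ma_method"),
                                  (self.rs_method, RS_METHODS, "rs_method"),
                                  (self.xnorm, XNORM_METHODS, "xnorm"),
                                  (self.ufs, UFS_METHODS + tuple(SCORERS), "ufs")):
            if value not in pool:
                raise ValueError(f"unknown {name} {value!r}")
        return self

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.ma_method, self.rs_method, self.xnorm, self.ufs)


def enumerate_combinations(exclude_xnorm=None,
                           ma_methods=MA_METHODS, rs_methods=RS_METHODS,
                           xnorm_methods=XNORM_METHODS,
                           ufs_methods=UFS_METHODS) -> list[CombinationSpec]:
    """Full Cartesian product of the four method lists, lexicographic order.

    ``exclude_xnorm`` removes cross-platform normalizers (e.g. the two the
    platform-entropy screen eliminates), shrinking the grid accordingly.
    """
    exclude = set(exclude_xnorm or ())
    unknown = exclude - set(xnorm_methods)
    if unknown:
        raise ValueError(f"unknown cross-platform method(s) in exclusion: {sorted(unknown)}")
    xn = [x for x in xnorm_methods if x not in exclude]
    return [CombinationSpec(*combo)
            for combo in product(ma_methods, rs_methods, xn, ufs_methods)]


# ---------------------------------------------------------------------------
# filters and ranking
# ---------------------------------------------------------------------------

def apply_filters(records, purity_min: float = 0.8, min_oe_min: float = 0.1,
                  entropy_min: float = 0.1, entropy_mode: str = "per_method"):
    """Drop combinations failing the selection filters (strict inequalities).

    ``records`` is a list of ``(CombinationSpec, EvalRecord)``. Rows must
    exceed ``purity_min`` and ``min_oe_min`` strictly. The platform-entropy
    screen removes whole cross-platform-normalization methods whose mean
    entropy is ≤ ``entropy_min`` (``entropy_mode="per_method"``, the
    default) or individual rows (``"per_combination"``). Returns the
    filtered list and a dict of per-filter drop counts.
    """
    if not records:
        raise ValueError("no records to filter")
    if entropy_mode not in ("per_method", "per_combination"):
        raise ValueError("entropy_mode must be 'per_method' or 'per_combination'")
    drops = {"purity": 0, "min_oe": 0, "entropy": 0}

    excluded_methods: set[str] = set()
    if entropy_mode == "per_method":
        by_method: dict[str, list[float]] = {}
        for combo, rec in records:
            by_method.setdefault(combo.xnorm, []).append(rec.entropy)
        excluded_methods = {m for m, v in by_method.items()
                            if not np.mean(v) > entropy_min}

    kept = []
    for combo, rec in records:
        if entropy_mode == "per_method":
            if combo.xnorm in excluded_methods:
                drops["entropy"] += 1
                continue
        elif not rec.entropy > entropy_min:
            drops["entropy"] += 1
            continue
        if not rec.purity > purity_min:
            drops["purity"] += 1
            continue
        if not rec.min_oe > min_oe_min:
            drops["min_oe"] += 1
            continue
        kept.append((combo, rec))
    return kept, drops


def rank_combinations(records) -> pd.DataFrame:
    """Equal-weight rank aggregation over the four statistic groups.

    Each statistic is ranked across combinations with its own direction
    (``bartels_rvn`` by ascending distance from its null expectation 2);
    ranks are averaged within each group, and the final score is the mean
    of the four group ranks (smaller = better). Ties in the final score are
    broken by the lexicographic order of the combination.
    """
    if not records:
        raise ValueError("no records to rank")
    combos = [c for c, _ in records]
    table = pd.DataFrame([r.as_dict() for _, r in records])
    for stat in EvalRecord.STAT_NAMES:
        if table[stat].isna().any():
            raise ValueError(f"missing statistic {stat!r} in records")

    stat_ranks = {}
    for stat in EvalRecord.STAT_NAMES:
        if stat == "bartels_rvn":
            key = np.abs(table[stat].to_numpy() - 2.0)
        elif HIGHER_BETTER[stat]:
            key = -table[stat].to_numpy()
        else:
            key = table[stat].to_numpy()
        stat_ranks[stat] = rankdata(key, method="average")

    group_ranks = np.column_stack([
        np.mean([stat_ranks[s] for s in group], axis=0) for group in STAT_GROUPS
    ])
    final = group_ranks.mean(axis=1)

    out = pd.DataFrame({
        "ma_method": [c.ma_method for c in combos],
        "rs_method": [c.rs_method for c in combos],
        "xnorm": [c.xnorm for c in combos],
        "ufs": [c.ufs for c in combos],
    })
    for i in range(4):
        out[f"group{i + 1}_rank"] = group_ranks[:, i]
    out["final_score"] = final
    out = pd.concat([out, table], axis=1)
    out = out.sort_values(
        ["final_score", "ma_method", "rs_method", "xnorm", "ufs"]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def stat_correlation_groups(records) -> pd.DataFrame:
    """Diagnostic: |Spearman correlation| matrix of the ranking statistics.

    Lets users verify on their own data the four-group structure that the
    ranking hard-codes.
    """
    table = pd.DataFrame([r.as_dict() for _, r in records])[list(EvalRecord.STAT_NAMES)]
    return table.corr(method="spearman").abs()


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """Clustering/selection settings shared by every grid cell."""

    k: int = 3
    n_resamples: int = 100
    subsample_frac: float = 0.8
    base_method: str = "hierarchical-ward"
    n_total_features: int = 1024
    n_bins: int = 8
    log_prior: float = 0.5
    cache_dir: str | None = None

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "cache_dir"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def normalize_rnaseq(counts: ExprMatrix, method: str, gene_anno: pd.DataFrame,
                     log_prior: float = 0.5) -> ExprMatrix:
    """Apply one of the grid's RNA-seq units, returning log2-scale data."""
    lengths = gene_anno["length_bp"]
    if method == "cpm":
        return units.cpm(counts, prior_count=log_prior, log_output=True)
    if method == "rpkm":
        linear = units.rpkm(counts, lengths)
        return ExprMatrix(np.log2(linear.data + log_prior), unit="log2_normalized")
    if method == "fpkm":
        linear = units.fpkm(counts, lengths)
        return ExprMatrix(np.log2(linear.data + log_prior), unit="log2_normalized")
    if method == "normTransform":
        return units.shifted_log(counts)
    if method == "voom":
        return units.voom_logcpm(counts, prior_count=log_prior)
    if method == "vst":
        return units.vst_closed_form(counts)
    raise ValueError(f"unknown RNA-seq method {method!r}")


def _cross_normalize(combo: CombinationSpec, ma: ExprMatrix, rs_norm: ExprMatrix,
                     counts: ExprMatrix):
    if combo.xnorm == "FSQN":
        rs_x = crossnorm.fsqn(rs_norm, ma)
        return crossnorm.merge_platforms(ma, rs_x)
    if combo.xnorm == "TDM":
        rs_x = crossnorm.tdm(counts, ma)
        return crossnorm.merge_platforms(ma, rs_x)
    if combo.xnorm == "quantile":
        merged, platform_of = crossnorm.merge_platforms(ma, rs_norm)
        return crossnorm.quantile_norm(merged), platform_of
    if combo.xnorm == "ComBat":
        merged, platform_of = crossnorm.merge_platforms(ma, rs_norm)
        return crossnorm.combat(merged, platform_of), platform_of
    raise ValueError(f"unknown cross-platform method {combo.xnorm!r}")


def run_combination(cohort: SimCohort, combo: CombinationSpec, config: GridConfig,
                    seed: int) -> EvalRecord:
    """Run one grid cell end to end and return its :class:`EvalRecord`."""
    combo.validate()
    if combo.ufs not in SCORERS:
        raise NotImplementedError(f"feature scorer {combo.ufs!r} has no implementation "
                                  "or registered plugin")
    ma = cohort.intensities_microarray  # mas5/rma arrive pre-summarized
    counts = cohort.counts_rnaseq
    rs_norm = normalize_rnaseq(counts, combo.rs_method, cohort.gene_anno,
                               log_prior=config.log_prior)
    merged, platform_of = _cross_normalize(combo, ma, rs_norm, counts)

    fspec = FeatureSelSpec(scorer=combo.ufs, n_total=config.n_total_features,
                           n_bins=config.n_bins)
    ckw = dict(n_resamples=config.n_resamples, subsample_frac=config.subsample_frac,
               base_method=config.base_method)

    cross_sel = as_frame(merged).loc[select_features(merged, fspec)]
    cross_res = consensus_cluster(cross_sel, config.k, seed=seed, **ckw)

    single_results = {}
    for p, mat in (("microarray", ma), ("rnaseq", rs_norm)):
        sel = as_frame(mat).loc[select_features(mat, fspec)]
        single_results[p] = consensus_cluster(sel, config.k, seed=seed + 1, **ckw)

    return evaluate_clustering(cross_res, single_results, platform_of)


def run_grid(cohort: SimCohort, combos, config: GridConfig | None = None,
             seed: int = 0):
    """Evaluate every combination; errors and unimplemented scorers are
    recorded, not raised.

    Returns ``(records, report)`` where ``records`` is the list of
    ``(CombinationSpec, EvalRecord)`` for successful cells and ``report``
    is a DataFrame with one row per requested combination (status ok /
    skipped / error plus reason). With ``config.cache_dir`` set, results
    are cached per combination keyed by combo + config hash + seed, and
    reruns reuse them.
    """
    config = config or GridConfig()
    cache = Path(config.cache_dir) if config.cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    records, rows = [], []
    for i, combo in enumerate(combos):
        combo_seed = (seed * 1_000_003 + i * 7919) % (2 ** 31 - 1)
        key = f"{'_'.join(combo.as_tuple())}-{config.content_hash()}-{combo_seed}"
        cache_file = cache / f"{key}.json" if cache else None
        status, reason, rec = "ok", "", None
        if cache_file is not None and cache_file.exists():
            payload = json.loads(cache_file.read_text())
            rec = EvalRecord(**payload)
            status = "cached"
        else:
            try:
                rec = run_combination(cohort, combo, config, combo_seed)
            except NotImplementedError as exc:
                status, reason = "skipped", "unimplemented"
            except Exception as exc:  # record and continue
                status, reason = "error", f"{type(exc).__name__}: {exc}"
            if rec is not None and cache_file is not None:
                cache_file.write_text(json.dumps(rec.as_dict()))
        if rec is not None:
            records.append((combo, rec))
        rows.append({**dict(zip(("ma_method", "rs_method", "xnorm", "ufs"),
                                combo.as_tuple())),
                     "status": status, "reason": reason})
    return records, pd.DataFrame(rows)
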