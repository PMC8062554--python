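"""TSV/JSON interchange for matrices, metadata and annotation.

Conventions: expression matrices are TSV with the gene id in the first
column and sample ids in the header; metadata is TSV with ``sample_id``,
``platform``, ``batch`` and ``label`` columns; gene annotation is TSV with
``gene_id`` and ``length_bp``. A JSON sidecar records the unit and the
generating configuration where applicable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExprMatrix, validate_meta


def read_expr_tsv(path, unit: str = "log2_normalized") -> ExprMatrix:
    """Read a gene × sample TSV, validating ids and numeric content."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups[:5]}")
    for col in frame.columns:
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = series.isna() & ~frame[col].isna()
        if bad.any():
            gene = frame.index[bad][0]
            raise ValueError(f"non-numeric cell in {path} at gene {gene!r}, "
                             f"sample {col!r}")
        if series.isna().any():
            gene = frame.index[series.isna()][0]
            raise ValueError(f"NA cell in {path} at gene {gene!r}, sample {col!r}")
        frame[col] = series
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        unit = json.loads(sidecar.read_text()).get("unit", unit)
    return ExprMatrix(frame, unit=unit)


def write_expr_tsv(expr: ExprMatrix, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    frame = expr.data if isinstance(expr, ExprMatrix) else pd.DataFrame(expr)
    frame.to_csv(path, sep="\t", index_label="gene_id")
    meta = {"unit": expr.unit if isinstance(expr, ExprMatrix) else "log2_normalized"}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, default=_jsonable))


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    validate_meta(meta)
    known = {"microarray", "rnaseq", "protein"}
    unknown = set(meta["platform"].unique()) - known
    if unknown:
        raise ValueError(f"unknown platform value(s) in {path}: {sorted(unknown)}")
    return meta


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    validate_meta(meta)
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_anno_tsv(path) -> pd.DataFrame:
    anno = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length_bp" not in anno.columns:
        raise ValueError(f"{path} missing required column 'length_bp'")
    if (anno["length_bp"] <= 0).any():
        bad = anno.index[anno["length_bp"] <= 0][0]
        raise ValueError(f"non-positive length_bp for gene {bad!r}")
    return anno


def write_anno_tsv(anno: pd.DataFrame, path) -> None:
    anno.to_csv(path, sep="\t", index_label="gene_id")


def _jsonable(obj):
    if is_dataclass(obj):
        return asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def write_cohort(cohort, out_dir) -> None:
    """Write a simulated cohort as the TSV/JSON bundle downstream CLIs read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expr_tsv(cohort.counts_rnaseq, out / "rnaseq_counts.tsv")
    write_expr_tsv(cohort.intensities_microarray, out / "microarray_log2.tsv")
    if cohort.protein is not None:
        write_expr_tsv(cohort.protein, out / "protein_log2.tsv")
    write_meta_tsv(cohort.meta, out / "meta.tsv")
    write_anno_tsv(cohort.gene_anno, out / "gene_anno.tsv")
    write_json({"config": asdict(cohort.config), "seed": cohort.config.seed},
               out / "sim_config.json")
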