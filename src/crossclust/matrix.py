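"""Core in-memory containers shared by every pipeline stage.

Expression data flow through the pipeline as genes × samples
:class:`pandas.DataFrame` objects wrapped in :class:`ExprMatrix`, which also
carries the measurement unit so that stages can refuse inputs on the wrong
scale (e.g. TDM wants raw counts, ComBat wants log2 values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Units an :class:`ExprMatrix` may declare.
UNITS = (
    "counts",          # raw RNA-seq counts (nonnegative integers)
    "linear",          # linear-scale normalized values (CPM/RPKM/FPKM)
    "log2_intensity",  # summarized microarray log2 intensities
    "log2_normalized", # any log2-scale normalized expression
    "zscore",          # per-gene standardized values
)

META_COLUMNS = ("platform", "batch", "label")


@dataclass
class ExprMatrix:
    """Genes × samples expression matrix with a declared unit.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of :data:`UNITS`.
    """

    data: pd.DataFrame
    unit: str = "log2_normalized"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, unit: str | None = None) -> "ExprMatrix":
        return ExprMatrix(data=data, unit=unit if unit is not None else self.unit)

    def copy(self) -> "ExprMatrix":
        return replace(self, data=self.data.copy())


def as_frame(x) -> pd.DataFrame:
    """Accept an ExprMatrix or a DataFrame and return the DataFrame."""
    if isinstance(x, ExprMatrix):
        return x.data
    if isinstance(x, pd.DataFrame):
        return x
    return pd.DataFrame(x)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check that a sample-metadata table has the required columns.

    The index holds sample ids; required columns are ``platform``, ``batch``
    and ``label`` (the main class label, possibly NA for unlabeled samples).
    Optional columns (``subtype``, ``confidence``, ``flipped`` …) pass
    through untouched.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing required column(s): {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return meta


def check_aligned(expr: ExprMatrix | pd.DataFrame, meta: pd.DataFrame) -> None:
    frame = as_frame(expr)
    if not frame.columns.equals(meta.index):
        missing = frame.columns.difference(meta.index).tolist()
        extra = meta.index.difference(frame.columns).tolist()
        raise ValueError(
            f"expression columns and metadata rows disagree "
            f"(missing from meta: {missing[:3]}, extra in meta: {extra[:3]})"
        )
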