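"""Per-gene fold-change tables from transcriptome and proteome screens.

Consumes already-normalised log2 fold-change tables (treated / control), one
row per gene (or probe / protein group, collapsed here to gene level), and
classifies each gene as decreased / increased / unaltered under strict
cutoffs: decreased means FC < down threshold, increased means FC > up
threshold; values exactly at a threshold are unaltered.  Default thresholds
are +/- 0.2 log2 units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RegulationCutoffs",
    "FoldChangeTable",
    "read_fc_table",
    "classify_regulation",
    "collapse_duplicates",
    "normalize_gene_id",
    "DECREASED",
    "INCREASED",
    "UNALTERED",
]

DECREASED = "decreased"
INCREASED = "increased"
UNALTERED = "unaltered"
CLASSES = (DECREASED, INCREASED, UNALTERED)


class SchemaError(ValueError):
    """Input table lacks a required column."""


def normalize_gene_id(gene_id: str) -> str:
    """Canonical join key: trimmed, uppercased gene symbol."""
    return str(gene_id).strip().upper()


@dataclass(frozen=True)
class RegulationCutoffs:
    """Strict log2 fold-change thresholds partitioning genes into classes."""

    down: float = -0.2
    up: float = 0.2

    def __post_init__(self) -> None:
        if not self.down < self.up:
            raise ValueError(
                f"down threshold ({self.down}) must be below up threshold ({self.up})"
            )


def classify_regulation(log2fc: float, cutoffs: RegulationCutoffs = RegulationCutoffs()) -> str:
    """Classify one log2 FC; inequalities are strict (boundary -> unaltered)."""
    if not math.isfinite(log2fc):
        raise ValueError(f"log2 fold change must be finite, got {log2fc}")
    if log2fc < cutoffs.down:
        return DECREASED
    if log2fc > cutoffs.up:
        return INCREASED
    return UNALTERED


def _classify_series(fc: pd.Series, cutoffs: RegulationCutoffs) -> pd.Series:
    return pd.Series(
        np.select([fc < cutoffs.down, fc > cutoffs.up], [DECREASED, INCREASED], UNALTERED),
        index=fc.index,
    )


def collapse_duplicates(rows: pd.DataFrame, policy: str = "extreme") -> pd.DataFrame:
    """Collapse rows sharing a gene id (case-insensitively) to one row each.

    ``extreme`` keeps the measurement of largest \\|log2fc\\| (ties: the more
    negative value); ``mean`` / ``median`` aggregate.  Row order follows first
    appearance of each gene.
    """
    if policy not in ("extreme", "mean", "median"):
        raise ValueError(f"unknown collapse policy {policy!r}")
    df = rows.copy()
    df["_key"] = df["gene_id"].map(normalize_gene_id)
    if not df["_key"].duplicated().any():
        return df.drop(columns="_key")
    if policy == "extreme":
        df["_abs"] = df["log2fc"].abs()
        df = (
            df.sort_values(["_abs", "log2fc"], ascending=[False, True], kind="mergesort")
            .drop_duplicates("_key", keep="first")
            .drop(columns="_abs")
        )
        df = df.sort_index()
    elif policy in ("mean", "median"):
        agg = df.groupby("_key", sort=False)["log2fc"].agg(policy)
        df = df.drop_duplicates("_key", keep="first").copy()
        df["log2fc"] = df["_key"].map(agg)
    else:
        raise ValueError(f"unknown collapse policy {policy!r}")
    return df.drop(columns="_key").reset_index(drop=True)


@dataclass
class FoldChangeTable:
    """Classified per-gene log2 fold changes on one platform.

    ``data`` has columns ``gene_id``, ``log2fc``, ``regulation``; gene ids
    are unique after collapsing (case-insensitively).
    """

    platform: str
    data: pd.DataFrame
    cutoffs: RegulationCutoffs = RegulationCutoffs()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        platform: str,
        cutoffs: RegulationCutoffs = RegulationCutoffs(),
        collapse: str = "extreme",
    ) -> "FoldChangeTable":
        df = df[["gene_id", "log2fc"]].copy()
        df["gene_id"] = df["gene_id"].astype(str).str.strip()
        df = collapse_duplicates(df, collapse)
        df["regulation"] = _classify_series(df["log2fc"], cutoffs)
        return cls(platform=platform, data=df.reset_index(drop=True), cutoffs=cutoffs)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_keys(self) -> set[str]:
        return set(self.data["gene_id"].map(normalize_gene_id))

    def class_counts(self) -> dict[str, int]:
        counts = self.data["regulation"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def reclassified(self, cutoffs: RegulationCutoffs) -> "FoldChangeTable":
        df = self.data[["gene_id", "log2fc"]].copy()
        df["regulation"] = _classify_series(df["log2fc"], cutoffs)
        return FoldChangeTable(platform=self.platform, data=df, cutoffs=cutoffs)

    def write(self, path: Union[str, Path]) -> None:
        """Canonical TSV: gene_id, log2fc (12 significant digits), class."""
        out = self.data.copy()
        out["log2fc"] = out["log2fc"].map(lambda v: format(v, ".12g"))
        out.to_csv(path, sep="\t", index=False)


def read_fc_table(
    path: Union[str, Path],
    platform: str,
    id_column: str = "gene_id",
    fc_column: str = "log2fc",
    fc_scale: str = "log2",
    sep: str | None = None,
    cutoffs: RegulationCutoffs = RegulationCutoffs(),
    collapse: str = "extreme",
) -> FoldChangeTable:
    """Read a TSV/CSV fold-change table and classify it.

    ``fc_scale="linear"`` converts to log2 on input (non-positive linear
    values cannot be log-transformed and are dropped).  Rows with missing ids
    or non-finite fold changes are dropped with a logged count.  Gzipped
    input is accepted; the delimiter is sniffed unless ``sep`` is given.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except OSError as exc:
        raise IOError(f"cannot read fold-change table {path}: {exc}") from exc
    missing = [c for c in (id_column, fc_column) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; available headers: {list(df.columns)}"
        )
    df = df[[id_column, fc_column]].rename(columns={id_column: "gene_id", fc_column: "log2fc"})
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["gene_id", "log2fc"])
    df = df[np.isfinite(df["log2fc"])]
    df = df[df["gene_id"].astype(str).str.strip() != ""]
    if fc_scale == "linear":
        df = df[df["log2fc"] > 0]
        df["log2fc"] = np.log2(df["log2fc"])
    elif fc_scale != "log2":
        raise ValueError(f"fc_scale must be 'log2' or 'linear', got {fc_scale!r}")
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d unusable row(s)", path, dropped)
    return FoldChangeTable.from_frame(df, platform, cutoffs, collapse)
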