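"""Seed-site enrichment across regulation classes and CDF-shift curves.

Two complementary views of the same question — do site-containing genes go
down after miRNA overexpression?

* **Fraction enrichment**: the fraction of site-containing genes within each
  regulation class (decreased / increased / unaltered), tested with an
  asymptotic chi-squared test of independence on a configurable contingency
  layout (no continuity correction by default).
* **Cumulative-fraction curves**: the empirical CDF of log2 fold change for
  the site-containing set against a control set (by default, all measured
  genes without a site).  A left shift of the site curve indicates
  repression; the maximum vertical gap is the two-sample KS D statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import CLASSES, DECREASED, INCREASED, UNALTERED, FoldChangeTable, normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateTableError",
    "EnrichmentResult",
    "CumulativeCurve",
    "fraction_enrichment",
    "enrichment_from_counts",
    "cumulative_fraction",
    "ks_test",
]

COMPARISONS = ("decreased_vs_rest", "decreased_vs_increased", "three_class")


class DegenerateTableError(ValueError):
    """The requested contingency layout has an empty row or column."""


@dataclass
class EnrichmentResult:
    """Per-class site fractions plus the chi-squared test on one layout."""

    comparison: str
    class_totals: dict[str, int]
    class_site_counts: dict[str, int]
    fractions: dict[str, float]
    table: np.ndarray  # rows = layout classes, cols = (site, no site)
    row_labels: tuple[str, ...]
    chi2: float
    dof: int
    p_value: float
    ignored_site_genes: int = 0

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "class_totals": self.class_totals,
            "class_site_counts": self.class_site_counts,
            "fractions": self.fractions,
            "table": self.table.tolist(),
            "row_labels": list(self.row_labels),
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
            "ignored_site_genes": self.ignored_site_genes,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _layout(
    site: Mapping[str, int], totals: Mapping[str, int], comparison: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    def row(label: str, n_site: int, n_total: int):
        return [n_site, n_total - n_site]

    if comparison == "decreased_vs_rest":
        rest_total = totals[INCREASED] + totals[UNALTERED]
        rest_site = site[INCREASED] + site[UNALTERED]
        table = [
            row(DECREASED, site[DECREASED], totals[DECREASED]),
            row("rest", rest_site, rest_total),
        ]
        labels = (DECREASED, "rest")
    elif comparison == "decreased_vs_increased":
        table = [
            row(DECREASED, site[DECREASED], totals[DECREASED]),
            row(INCREASED, site[INCREASED], totals[INCREASED]),
        ]
        labels = (DECREASED, INCREASED)
    elif comparison == "three_class":
        table = [row(c, site[c], totals[c]) for c in CLASSES]
        labels = CLASSES
    else:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    return np.asarray(table, dtype=float), labels


def enrichment_from_counts(
    site_counts: Mapping[str, int],
    totals: Mapping[str, int],
    comparison: str = "decreased_vs_rest",
    correction: bool = False,
    ignored_site_genes: int = 0,
) -> EnrichmentResult:
    """Enrichment test from pre-tabulated per-class counts.

    ``site_counts[c]`` is the number of site-containing genes in class ``c``
    and ``totals[c]`` the class size.  Classes missing from the mappings are
    treated as empty.
    """
    site = {c: int(site_counts.get(c, 0)) for c in CLASSES}
    totals = {c: int(totals.get(c, 0)) for c in CLASSES}
    for c in CLASSES:
        if site[c] > totals[c]:
            raise ValueError(f"class {c!r}: site count {site[c]} exceeds total {totals[c]}")
    table, labels = _layout(site, totals, comparison)
    if (table.sum(axis=1) == 0).any():
        hint = " (try comparison='decreased_vs_rest')" if comparison == "three_class" else ""
        empty = [l for l, s in zip(labels, table.sum(axis=1)) if s == 0]
        raise DegenerateTableError(f"empty class(es) {empty} in {comparison} layout{hint}")
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            f"degenerate {comparison} table: all genes on one side of the site split"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    fractions = {c: site[c] / totals[c] if totals[c] else float("nan") for c in CLASSES}
    return EnrichmentResult(
        comparison=comparison,
        class_totals=totals,
        class_site_counts=site,
        fractions=fractions,
        table=table,
        row_labels=labels,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        ignored_site_genes=ignored_site_genes,
    )


def fraction_enrichment(
    table: FoldChangeTable,
    site_genes: Iterable[str],
    comparison: str = "decreased_vs_rest",
    correction: bool = False,
) -> EnrichmentResult:
    """Site-containing fraction per regulation class + chi-squared test.

    Site genes absent from the measured table are ignored (with a logged
    count): the measurable universe is the table.
    """
    site_keys = {normalize_gene_id(g) for g in site_genes}
    df = table.data
    keys = df["gene_id"].map(normalize_gene_id)
    has_site = keys.isin(site_keys)
    ignored = len(site_keys - set(keys))
    if ignored:
        logger.info(
            "%d site gene(s) absent from the %s table were ignored", ignored, table.platform
        )
    totals = df["regulation"].value_counts().to_dict()
    site_counts = df.loc[has_site, "regulation"].value_counts().to_dict()
    return enrichment_from_counts(
        site_counts, totals, comparison, correction, ignored_site_genes=ignored
    )


@dataclass
class CumulativeCurve:
    """Paired empirical CDFs of log2 FC for a gene set and its control.

    ``x`` holds every observed fold change (ascending); ``y_in_set`` /
    ``y_out_set`` are the inclusive (<=) cumulative fractions.  The maximum
    vertical gap between the curves is the KS D statistic.
    """

    x: np.ndarray
    y_in_set: np.ndarray
    y_out_set: np.ndarray
    n_set: int
    n_control: int
    max_vertical_gap: float
    set_values: np.ndarray = field(repr=False, default=None)
    control_values: np.ndarray = field(repr=False, default=None)
    set_label: str = "site"
    control_label: str = "no site"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"log2fc": self.x, "y_set": self.y_in_set, "y_control": self.y_out_set}
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def cumulative_fraction(
    table: FoldChangeTable,
    gene_set: Iterable[str],
    control: Union[str, Iterable[str]] = "complement",
    set_label: str = "site",
) -> CumulativeCurve:
    """Cumulative fold-change fraction curves for a gene set vs control.

    At each observed fold change ``x``, the curve value is the fraction of
    the set whose log2 FC is <= x; the control is either the complement of
    the set within the table (default) or an explicit gene set.
    """
    df = table.data
    keys = df["gene_id"].map(normalize_gene_id)
    set_keys = {normalize_gene_id(g) for g in gene_set}
    in_set = keys.isin(set_keys)
    set_values = df.loc[in_set, "log2fc"].to_numpy(float)
    if set_values.size == 0:
        raise ValueError(
            f"gene set {set_label!r} has no overlap with the {table.platform} table"
        )
    if isinstance(control, str) and control == "complement":
        control_values = df.loc[~in_set, "log2fc"].to_numpy(float)
        control_label = f"not {set_label}"
    else:
        ctrl_keys = {normalize_gene_id(g) for g in control}
        control_values = df.loc[keys.isin(ctrl_keys), "log2fc"].to_numpy(float)
        control_label = "control"
    if control_values.size == 0:
        raise ValueError(f"control set {control_label!r} has no overlap with the table")
    set_sorted = np.sort(set_values)
    ctrl_sorted = np.sort(control_values)
    x = np.unique(np.concatenate([set_sorted, ctrl_sorted]))
    y_set = np.searchsorted(set_sorted, x, side="right") / set_sorted.size
    y_ctrl = np.searchsorted(ctrl_sorted, x, side="right") / ctrl_sorted.size
    d = float(np.max(np.abs(y_set - y_ctrl)))
    return CumulativeCurve(
        x=x,
        y_in_set=y_set,
        y_out_set=y_ctrl,
        n_set=set_sorted.size,
        n_control=ctrl_sorted.size,
        max_vertical_gap=d,
        set_values=set_sorted,
        control_values=ctrl_sorted,
        set_label=set_label,
        control_label=control_label,
    )


def ks_test(curve: CumulativeCurve) -> float:
    """Two-sided two-sample KS p-value for the distributions behind a curve."""
    if curve.n_set < 2 or curve.n_control < 2:
        raise ValueError(
            f"KS test needs >= 2 values per set (got {curve.n_set} and {curve.n_control})"
        )
    return float(stats.ks_2samp(curve.set_values, curve.control_values).pvalue)
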