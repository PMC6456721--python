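"""Dual-omics target calling and prediction-set intersections.

Joins the transcriptome and proteome screens on gene symbol, flags genes
whose 3'UTR carries a seed site, and calls candidate direct targets: genes
decreased on *both* platforms beyond the cutoff that also carry a site.
Candidates are ranked by protein log2 FC (most repressed first) — the
proteome being the phenotype-proximal readout — with ties broken by mRNA FC
and then gene id.

Also tabulates Venn-region counts across per-algorithm predicted-target
lists (e.g. PicTar / TargetScan / DIANA-microT / miRanda), consumed as plain
gene-symbol files.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .omics_io import FoldChangeTable, RegulationCutoffs, normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "join_omics",
    "call_candidates",
    "venn_counts",
    "read_gene_list",
]


def read_gene_list(path: Union[str, Path]) -> set[str]:
    """Read a plain-text gene list, one symbol per line; blank lines skipped."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def join_omics(
    mrna: FoldChangeTable,
    protein: FoldChangeTable,
    site_genes: Iterable[str] = (),
    site_classes: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Inner join of the two screens on gene symbol (case-insensitive).

    Returns one row per gene measured on both platforms with columns
    ``gene_id``, ``mrna_log2fc``, ``protein_log2fc``, ``has_site`` and
    ``site_classes`` (comma-joined class labels, empty if none).
    """
    m = mrna.data[["gene_id", "log2fc"]].rename(columns={"log2fc": "mrna_log2fc"}).copy()
    p = protein.data[["gene_id", "log2fc"]].rename(columns={"log2fc": "protein_log2fc"}).copy()
    m["_key"] = m["gene_id"].map(normalize_gene_id)
    p["_key"] = p["gene_id"].map(normalize_gene_id)
    joined = m.merge(p.drop(columns="gene_id"), on="_key", how="inner")
    if joined.empty:
        raise ValueError(
            "transcriptome/proteome join is empty: gene id spaces do not overlap "
            "(check symbol conventions on both platforms)"
        )
    site_keys = {normalize_gene_id(g) for g in site_genes}
    joined["has_site"] = joined["_key"].isin(site_keys)
    if site_classes is not None:
        lookup = {
            normalize_gene_id(g): ",".join(sorted(set(map(str, cls))))
            for g, cls in site_classes.items()
        }
        joined["site_classes"] = joined["_key"].map(lookup).fillna("")
    else:
        joined["site_classes"] = ""
    return joined.drop(columns="_key").reset_index(drop=True)


def call_candidates(
    joined: pd.DataFrame,
    cutoffs: RegulationCutoffs = RegulationCutoffs(),
    require_site: bool = True,
) -> pd.DataFrame:
    """Candidate direct targets: strict double decrease (+ site, optionally).

    A gene qualifies when mRNA and protein log2 FC are both strictly below
    the down threshold.  Output columns: gene_id, mrna_log2fc,
    protein_log2fc, rank (1 = most repressed at the protein level).
    """
    if joined.empty:
        raise ValueError("joined table is empty; run join_omics first")
    mask = (joined["mrna_log2fc"] < cutoffs.down) & (joined["protein_log2fc"] < cutoffs.down)
    if require_site:
        mask &= joined["has_site"]
    hits = joined.loc[mask, ["gene_id", "mrna_log2fc", "protein_log2fc"]].copy()
    hits["_key"] = hits["gene_id"].map(normalize_gene_id)
    hits = hits.sort_values(
        ["protein_log2fc", "mrna_log2fc", "_key"], kind="mergesort"
    ).drop(columns="_key")
    hits["rank"] = range(1, len(hits) + 1)
    return hits.reset_index(drop=True)


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict:
    """Membership-region counts for 2-6 gene sets.

    Returns a dict with ``set_sizes``, ``regions`` (keys are '&'-joined
    sorted set names, one per non-empty membership combination), ``union``
    and ``intersection`` (the all-sets region count).
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("venn_counts needs at least 2 sets")
    if len(names) > 6:
        raise ValueError(f"refusing {len(names)} sets: region listing is unreadable beyond 6")
    norm = {name: {normalize_gene_id(g) for g in members} for name, members in sets.items()}
    universe = set().union(*norm.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions["&".join(combo)] = 0
    for g in universe:
        membership = tuple(n for n in names if g in norm[n])
        regions["&".join(membership)] += 1
    return {
        "set_sizes": {n: len(norm[n]) for n in names},
        "regions": regions,
        "union": len(universe),
        "intersection": regions["&".join(names)],
    }
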