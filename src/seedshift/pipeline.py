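"""End-to-end orchestration: scan -> classify -> enrich -> join -> candidates.

``run_pipeline`` wires the stage functions together exactly as a user would
call them individually, writes every stage output under one directory, and
produces a diffable ``summary.json`` (timestamps go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from . import __version__
from .enrichment import cumulative_fraction, fraction_enrichment, ks_test
from .integration import call_candidates, join_omics
from .omics_io import RegulationCutoffs, read_fc_table
from .seedscan import (
    CANONICAL_CLASSES,
    MatureMiRNA,
    SiteClass,
    derive_site_patterns,
    scan_collection,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Inputs and knobs of one full pipeline run."""

    utr_fasta: Union[str, Path]
    mrna_table: Union[str, Path]
    protein_table: Union[str, Path]
    mirna_sequence: str
    mirna_name: str = "miRNA"
    out_dir: Union[str, Path] = "seedshift_out"
    cutoffs: RegulationCutoffs = field(default_factory=RegulationCutoffs)
    min_site_class: str = "7mer-1a"
    comparison: str = "decreased_vs_rest"
    permissive_6mer: bool = False
    id_column: str = "gene_id"
    fc_column: str = "log2fc"
    require_site: bool = True

    def classes(self):
        return None if self.permissive_6mer else CANONICAL_CLASSES


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("scan")
    mirna = MatureMiRNA(config.mirna_name, config.mirna_sequence)
    patterns = derive_site_patterns(mirna)
    scan = scan_collection(config.utr_fasta, patterns, config.classes())
    scan.to_bed(out / "sites.bed")
    scan.counts_json(out / "site_counts.json")
    site_genes = scan.gene_set(SiteClass.from_label(config.min_site_class))

    _stage("classify")
    mrna = read_fc_table(
        config.mrna_table, "transcript", config.id_column, config.fc_column, cutoffs=config.cutoffs
    )
    protein = read_fc_table(
        config.protein_table, "protein", config.id_column, config.fc_column, cutoffs=config.cutoffs
    )
    mrna.write(out / "mrna_classified.tsv")
    protein.write(out / "protein_classified.tsv")

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seedshift_version": __version__,
        "parameters": {
            "mirna_name": config.mirna_name,
            "mirna_sequence": config.mirna_sequence,
            "cutoffs": {"down": config.cutoffs.down, "up": config.cutoffs.up},
            "min_site_class": config.min_site_class,
            "comparison": config.comparison,
            "permissive_6mer": config.permissive_6mer,
        },
        "scan": {
            "n_genes_scanned": len(scan.counts),
            "n_sites": scan.total_sites,
            "n_site_genes": len(site_genes),
        },
    }

    _stage("enrichment")
    enrich = {}
    for label, table in (("transcript", mrna), ("protein", protein)):
        res = fraction_enrichment(table, site_genes, config.comparison)
        res.write_json(out / f"enrichment_{label}.json")
        enrich[label] = {
            "class_counts": table.class_counts(),
            "site_counts": res.class_site_counts,
            "fractions": res.fractions,
            "chi2": res.chi2,
            "dof": res.dof,
            "p_value": res.p_value,
        }
    summary["enrichment"] = enrich

    _stage("curves")
    curves = {}
    for label, table in (("transcript", mrna), ("protein", protein)):
        curve = cumulative_fraction(table, site_genes)
        curve.write_tsv(out / f"curve_{label}.tsv")
        curves[label] = {
            "n_set": curve.n_set,
            "n_control": curve.n_control,
            "D": curve.max_vertical_gap,
            "ks_p": ks_test(curve),
        }
    summary["cumulative_curves"] = curves

    _stage("integrate")
    site_classes = {
        g: [c for c, n in cnt.items() if n] for g, cnt in scan.counts.items() if cnt
    }
    joined = join_omics(mrna, protein, site_genes, site_classes)
    joined.to_csv(out / "joined.tsv", sep="\t", index=False, float_format="%.12g")
    candidates = call_candidates(joined, config.cutoffs, require_site=config.require_site)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.12g")
    summary["integration"] = {
        "n_joined": int(len(joined)),
        "n_joined_with_site": int(joined["has_site"].sum()),
        "n_candidates": int(len(candidates)),
        "candidates": [
            {
                "gene_id": r.gene_id,
                "mrna_log2fc": float(r.mrna_log2fc),
                "protein_log2fc": float(r.protein_log2fc),
                "rank": int(r.rank),
            }
            for r in candidates.itertuples()
        ],
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
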