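"""Synthetic fixtures with known ground truth for the whole pipeline.

Emulates the statistical structure of a miRNA-overexpression target screen
and a two-group miRNA array:

* 3'UTRs as i.i.d. uniform {A,C,G,U} background with one seed site of a
  configured class planted per target gene at a random position.  Chance
  occurrences of the patterns in the background are *recorded, not
  scrubbed* (scrubbing would distort background composition), so the site
  ground truth is planted plus chance sites.
* A repression model: target genes shift negatively in mRNA log2 FC
  (mean ``mrna_shift``) and, attenuated and correlated, in protein log2 FC
  (mean ``protein_shift``), with Gaussian noise; non-targets are centred at
  zero.
* Per-algorithm predicted-target lists as noisy views of the true targets.
* A Ct matrix with one planted differential miRNA whose group-B values are
  shifted by ``ct_delta_delta`` cycles and whose non-detects concentrate in
  the shifted (low-expression) group — the detected-mostly-in-one-group
  pattern.

All randomness flows from one ``numpy`` Generator seeded by the config, so
identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import seedscan
from .omics_io import FoldChangeTable, RegulationCutoffs
from .profiling import CtMatrix
from .seedscan import (
    MIR_324_5P,
    MatureMiRNA,
    SitePatternSet,
    UTRRecord,
    derive_site_patterns,
    scan_utr,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_utrs",
    "simulate_overexpression",
    "simulate_prediction_sets",
    "simulate_ct_matrix",
    "write_dataset",
]

_NT = np.frombuffer(b"ACGU", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to its conditions.

    Fold-change model: ``n_targets`` of ``n_genes`` genes are true targets
    with mean mRNA shift ``mrna_shift`` and mean protein shift
    ``protein_shift`` (log2 units); per-platform Gaussian noise has sd
    ``noise_sd``; ``protein_mrna_correlation`` couples the protein residual
    to the mRNA residual.  Ct model: two groups of ``ct_n_per_group``
    samples over ``n_mirnas`` miRNAs; the planted miRNA's group-B Cts are
    shifted by ``ct_delta_delta`` cycles and its non-detects drawn with
    ``planted_nondetect_prob`` (per group) instead of the background
    ``ct_nondetect_prob``.
    """

    seed: int = 0
    # --- UTR / fold-change screen ---
    n_genes: int = 1000
    n_targets: int = 100
    utr_length: tuple[int, int] = (200, 2000)
    mrna_shift: float = -0.5
    protein_shift: float = -0.35
    protein_mrna_correlation: float = 0.8
    noise_sd: float = 0.15
    site_classes: tuple[str, ...] = ("7mer-m8",)
    platform_dropout: float = 0.0
    mirna_name: str = "miR-324-5p"
    mirna_sequence: str = MIR_324_5P
    # --- prediction lists ---
    algorithms: tuple[str, ...] = ("PicTar", "TargetScan", "DIANA-microT", "miRanda")
    prediction_sensitivity: float = 0.6
    prediction_background_rate: float = 0.1
    # --- Ct screen ---
    n_mirnas: int = 96
    ct_n_per_group: int = 10
    ct_delta_delta: float = 3.0
    ct_noise_sd: float = 0.5
    ct_nondetect_prob: tuple[float, float] = (0.02, 0.02)
    planted_nondetect_prob: tuple[float, float] = (0.0, 0.6)
    ct_max_cycles: float = 40.0

    def __post_init__(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets must not exceed n_genes")
        if self.noise_sd <= 0 or self.ct_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.utr_length[0] > self.utr_length[1] or self.utr_length[0] < 30:
            raise ValueError("utr_length must be a (min >= 30, max) range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    target_genes: list[str] = field(default_factory=list)
    planted_sites: list[dict] = field(default_factory=list)
    chance_sites: list[dict] = field(default_factory=list)
    true_mrna_shift: dict[str, float] = field(default_factory=dict)
    true_protein_shift: dict[str, float] = field(default_factory=dict)
    site_genes: list[str] = field(default_factory=list)
    differential_mirna: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_utr(rng: np.random.Generator, length: int) -> str:
    return _NT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_utrs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[UTRRecord], GroundTruth]:
    """Random-background UTRs with one planted site per target gene.

    Gene ids are ``G0001``..; targets are a random subset.  Ground truth
    records planted sites and every chance site the scanner finds, and
    ``site_genes`` = genes with >= 1 site of any canonical (7mer-1a or
    stronger) class.
    """
    rng = config.rng() if rng is None else rng
    patterns = derive_site_patterns(MatureMiRNA(config.mirna_name, config.mirna_sequence))
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    target_idx = set(rng.choice(config.n_genes, size=config.n_targets, replace=False).tolist())
    lo, hi = config.utr_length
    records: list[UTRRecord] = []
    truth = GroundTruth()
    planted_lookup: dict[tuple[str, int], str] = {}
    for i, gene in enumerate(genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_utr(rng, length)
        if i in target_idx:
            cls = seedscan.SiteClass.from_label(
                config.site_classes[int(rng.integers(0, len(config.site_classes)))]
            )
            pat = patterns[cls]
            pos = int(rng.integers(0, length - len(pat) + 1))  # 0-based
            seq = seq[:pos] + pat + seq[pos + len(pat):]
            truth.target_genes.append(gene)
            truth.planted_sites.append(
                {"gene_id": gene, "start": pos + 1, "end": pos + len(pat), "site_class": cls.value}
            )
            planted_lookup[(gene, pos + 1)] = cls.value
        records.append(UTRRecord(gene_id=gene, sequence=seq))
    # record chance sites (and site-gene truth) by scanning what was emitted
    site_genes: set[str] = set()
    for rec in records:
        for s in scan_utr(rec, patterns):
            if s.site_class >= seedscan.SiteClass.SEVEN_MER_1A:
                site_genes.add(rec.gene_id)
            if (rec.gene_id, s.start) not in planted_lookup:
                truth.chance_sites.append(
                    {
                        "gene_id": rec.gene_id,
                        "start": s.start,
                        "end": s.end,
                        "site_class": s.site_class.value,
                    }
                )
    truth.site_genes = sorted(site_genes)
    return records, truth


def simulate_overexpression(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    cutoffs: RegulationCutoffs = RegulationCutoffs(),
) -> tuple[FoldChangeTable, FoldChangeTable]:
    """Paired mRNA / protein fold-change tables under the repression model.

    For gene g with mRNA mean m_g (``mrna_shift`` for targets, else 0) and
    protein mean p_g, the draws are::

        mrna_g    = m_g + e_g,                      e_g ~ N(0, sd^2)
        protein_g = p_g + rho * s * e_g + sqrt(1 - rho^2) * f_g

    with f_g ~ N(0, sd^2), rho the mRNA-protein correlation and
    s = |protein_shift / mrna_shift| the attenuation of transcript changes
    at the protein level.  Target means are thus exact in expectation on
    both platforms; in the noiseless, fully correlated limit every target
    sits exactly at its shift.  ``platform_dropout`` removes a random gene
    fraction from each platform independently (partial screen overlap).
    """
    rng = config.rng() if rng is None else rng
    genes = sorted(truth.true_mrna_shift) if truth.true_mrna_shift else None
    if genes is None:
        width = max(4, len(str(config.n_genes)))
        genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    is_target = np.array([g in set(truth.target_genes) for g in genes])
    mu_m = np.where(is_target, config.mrna_shift, 0.0)
    mu_p = np.where(is_target, config.protein_shift, 0.0)
    sd = config.noise_sd
    rho = config.protein_mrna_correlation
    s = abs(config.protein_shift / config.mrna_shift) if config.mrna_shift else 1.0
    e = rng.normal(0.0, sd, size=len(genes))
    f = rng.normal(0.0, sd, size=len(genes))
    mrna = mu_m + e
    protein = mu_p + rho * s * e + np.sqrt(max(0.0, 1.0 - rho**2)) * f
    truth.true_mrna_shift = {g: float(m) for g, m in zip(genes, mu_m)}
    truth.true_protein_shift = {g: float(p) for g, p in zip(genes, mu_p)}
    keep_m = rng.random(len(genes)) >= config.platform_dropout
    keep_p = rng.random(len(genes)) >= config.platform_dropout
    mrna_df = pd.DataFrame({"gene_id": np.array(genes)[keep_m], "log2fc": mrna[keep_m]})
    prot_df = pd.DataFrame({"gene_id": np.array(genes)[keep_p], "log2fc": protein[keep_p]})
    return (
        FoldChangeTable.from_frame(mrna_df, "transcript", cutoffs),
        FoldChangeTable.from_frame(prot_df, "protein", cutoffs),
    )


def simulate_prediction_sets(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator | None = None
) -> dict[str, set[str]]:
    """Per-algorithm predicted-target lists as noisy views of the truth.

    Each algorithm recovers each true target with probability
    ``prediction_sensitivity`` and adds each non-target with probability
    ``prediction_background_rate`` — emulating the poor inter-algorithm
    agreement of sequence-based predictors.
    """
    rng = config.rng() if rng is None else rng
    targets = sorted(truth.target_genes)
    all_genes = sorted(truth.true_mrna_shift) if truth.true_mrna_shift else targets
    non_targets = [g for g in all_genes if g not in set(targets)]
    sets: dict[str, set[str]] = {}
    for alg in config.algorithms:
        hit = rng.random(len(targets)) < config.prediction_sensitivity
        noise = rng.random(len(non_targets)) < config.prediction_background_rate
        sets[alg] = {g for g, h in zip(targets, hit) if h} | {
            g for g, h in zip(non_targets, noise) if h
        }
    return sets


def simulate_ct_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CtMatrix, GroundTruth]:
    """Two-group Ct matrix with one planted differential miRNA.

    Background Cts are N(mu_m, ct_noise_sd^2) per miRNA with mu_m uniform in
    [22, 32]; the planted miRNA's group-B Cts are shifted by
    ``ct_delta_delta`` cycles (less expression in B) and its non-detects
    are drawn with the asymmetric ``planted_nondetect_prob``.  Values are
    clipped to (5, max_cycles].
    """
    rng = config.rng() if rng is None else rng
    if config.ct_n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    n, m = config.n_mirnas, config.ct_n_per_group
    mirnas = [f"miR-sim-{i + 1:03d}" for i in range(n)]
    planted = int(rng.integers(0, n))
    samples = [f"A{j + 1:02d}" for j in range(m)] + [f"B{j + 1:02d}" for j in range(m)]
    groups = pd.Series(["A"] * m + ["B"] * m, index=samples, name="group")
    mu = rng.uniform(22.0, 32.0, size=n)
    values = rng.normal(mu[:, None], config.ct_noise_sd, size=(n, 2 * m))
    values[planted, m:] += config.ct_delta_delta
    values = np.clip(values, 5.0, config.ct_max_cycles)
    pA, pB = config.ct_nondetect_prob
    prob = np.empty((n, 2 * m))
    prob[:, :m] = pA
    prob[:, m:] = pB
    prob[planted, :m] = config.planted_nondetect_prob[0]
    prob[planted, m:] = config.planted_nondetect_prob[1]
    detected = rng.random((n, 2 * m)) >= prob
    vals = pd.DataFrame(np.round(values, 3), index=mirnas, columns=samples)
    det = pd.DataFrame(detected, index=mirnas, columns=samples)
    vals = vals.where(det)
    truth = GroundTruth(differential_mirna=mirnas[planted])
    return (
        CtMatrix(values=vals, detected=det, groups=groups, max_cycles=config.ct_max_cycles),
        truth,
    )


def _write_fasta(records: list[UTRRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_dataset(config: SimulationConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Generate and write the complete synthetic dataset.

    Emits ``utrs.fasta``, ``mrna_fc.tsv``, ``protein_fc.tsv``,
    ``predicted_<algorithm>.txt``, ``ct_matrix.csv`` + ``groups.tsv`` and a
    ``truth.json`` manifest.  Identical configs produce byte-identical
    files.  Returns a name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    records, truth = simulate_utrs(config, rng)
    mrna, protein = simulate_overexpression(config, truth, rng)
    predictions = simulate_prediction_sets(config, truth, rng)
    ct, ct_truth = simulate_ct_matrix(config, rng)
    truth.differential_mirna = ct_truth.differential_mirna

    paths: dict[str, Path] = {}
    paths["utrs"] = out / "utrs.fasta"
    _write_fasta(records, paths["utrs"])
    paths["mrna"] = out / "mrna_fc.tsv"
    mrna.write(paths["mrna"])
    paths["protein"] = out / "protein_fc.tsv"
    protein.write(paths["protein"])
    for alg, members in predictions.items():
        key = f"predicted_{alg}"
        slug = alg.lower().replace("-", "_")
        paths[key] = out / f"predicted_{slug}.txt"
        paths[key].write_text("".join(g + "\n" for g in sorted(members)))
    paths["ct_matrix"] = out / "ct_matrix.csv"
    ct.write_csv(paths["ct_matrix"])
    paths["groups"] = out / "groups.tsv"
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in ct.groups.items():
            fh.write(f"{sample}\t{group}\n")
    paths["truth"] = out / "truth.json"
    truth.write_json(paths["truth"])
    return paths
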