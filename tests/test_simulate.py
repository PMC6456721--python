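"""Synthetic-data generator: determinism, planted truth, null behaviour."""

import json

import numpy as np
import pytest
from scipy import stats

from seedshift.omics_io import read_fc_table
from seedshift.profiling import CtMatrix
from seedshift.seedscan import (
    MatureMiRNA,
    SiteClass,
    derive_site_patterns,
    read_utr_fasta,
    scan_utr,
)
from seedshift.simulate import (
    SimulationConfig,
    simulate_ct_matrix,
    simulate_overexpression,
    simulate_prediction_sets,
    simulate_utrs,
    write_dataset,
)

SMALL = dict(n_genes=120, n_targets=20, utr_length=(150, 400), n_mirnas=24, ct_n_per_group=5)


def small_config(**overrides):
    return SimulationConfig(**{**SMALL, **overrides})


class TestSimulateUtrs:
    def test_planted_site_is_rediscovered(self):
        cfg = small_config(seed=7)
        records, truth = simulate_utrs(cfg)
        patterns = derive_site_patterns(MatureMiRNA(cfg.mirna_name, cfg.mirna_sequence))
        by_gene = {r.gene_id: r for r in records}
        for planted in truth.planted_sites:
            sites = scan_utr(by_gene[planted["gene_id"]], patterns)
            found = [
                s
                for s in sites
                if s.start == planted["start"]
                and SiteClass.from_label(s.site_class).rank
                >= SiteClass.from_label(planted["site_class"]).rank
            ]
            assert found, f"planted site not recovered for {planted['gene_id']}"

    def test_no_targets_only_chance_sites(self):
        _, truth = simulate_utrs(small_config(seed=3, n_targets=0))
        assert truth.target_genes == [] and truth.planted_sites == []
        # site genes, if any, are chance occurrences
        chance_genes = {s["gene_id"] for s in truth.chance_sites}
        assert set(truth.site_genes) <= chance_genes

    def test_chance_7mer_frequency_near_null_expectation(self):
        """Background pattern hits follow the (1/4)^7 per-position binomial."""
        cfg = SimulationConfig(seed=11, n_genes=500, n_targets=0, utr_length=(2000, 2000))
        records, _ = simulate_utrs(cfg)
        patterns = derive_site_patterns(MatureMiRNA(cfg.mirna_name, cfg.mirna_sequence))
        pat = patterns[SiteClass.SEVEN_MER_M8]
        hits = sum(rec.sequence.count(pat) for rec in records)
        n_pos = sum(len(rec.sequence) - len(pat) + 1 for rec in records)
        p = 0.25 ** len(pat)
        expected = n_pos * p
        sd = np.sqrt(n_pos * p * (1 - p))
        assert abs(hits - expected) <= 3 * sd

    def test_target_mean_shift_within_clt_bound(self):
        cfg = SimulationConfig(seed=5)  # defaults: 1000 genes, 100 targets
        rng = cfg.rng()
        _, truth = simulate_utrs(cfg, rng)
        mrna, _ = simulate_overexpression(cfg, truth, rng)
        fc = mrna.data.set_index("gene_id")["log2fc"]
        target_mean = fc.loc[[g for g in truth.target_genes if g in fc.index]].mean()
        bound = 3 * cfg.noise_sd / np.sqrt(cfg.n_targets)
        assert abs(target_mean - cfg.mrna_shift) <= bound


class TestOverexpression:
    def test_noiseless_limit_recovers_exact_shifts(self):
        cfg = small_config(seed=2, noise_sd=1e-9, protein_mrna_correlation=1.0)
        rng = cfg.rng()
        _, truth = simulate_utrs(cfg, rng)
        mrna, protein = simulate_overexpression(cfg, truth, rng)
        m = mrna.data.set_index("gene_id")["log2fc"]
        p = protein.data.set_index("gene_id")["log2fc"]
        for g in truth.target_genes:
            assert m[g] == pytest.approx(cfg.mrna_shift, abs=1e-6)
            assert p[g] == pytest.approx(cfg.protein_shift, abs=1e-6)

    def test_dropout_shrinks_platforms_independently(self):
        cfg = small_config(seed=9, platform_dropout=0.3)
        rng = cfg.rng()
        _, truth = simulate_utrs(cfg, rng)
        mrna, protein = simulate_overexpression(cfg, truth, rng)
        assert len(mrna) < cfg.n_genes and len(protein) < cfg.n_genes
        assert set(mrna.data.gene_id) != set(protein.data.gene_id)


class TestCtSimulation:
    def test_planted_mirna_separates_groups(self):
        cfg = small_config(seed=4, ct_nondetect_prob=(0.0, 0.0), planted_nondetect_prob=(0.0, 0.0))
        ct, truth = simulate_ct_matrix(cfg)
        row = ct.values.loc[truth.differential_mirna]
        a = row[[s for s in row.index if s.startswith("A")]].mean()
        b = row[[s for s in row.index if s.startswith("B")]].mean()
        assert b - a == pytest.approx(cfg.ct_delta_delta, abs=1.0)

    def test_nondetect_asymmetry_visible_in_rates(self):
        cfg = small_config(seed=6, planted_nondetect_prob=(0.1, 0.9), ct_n_per_group=10)
        ct, truth = simulate_ct_matrix(cfg)
        rates = ct.detection_rates().loc[truth.differential_mirna]
        assert rates["A"] > rates["B"]

    def test_null_welch_p_roughly_uniform_over_seeds(self):
        """With no planted shift the planted miRNA's p-value is null-distributed."""
        pvals = []
        for seed in range(60):
            cfg = small_config(
                seed=seed,
                ct_delta_delta=0.0,
                ct_nondetect_prob=(0.0, 0.0),
                planted_nondetect_prob=(0.0, 0.0),
                n_mirnas=6,
            )
            ct, truth = simulate_ct_matrix(cfg)
            from seedshift.profiling import differential_expression, normalize_global_mean

            de = differential_expression(normalize_global_mean(ct))
            pvals.append(de.loc[truth.differential_mirna, "p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWriteDataset:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = small_config(seed=13)
        p1 = write_dataset(cfg, tmp_path / "run1")
        p2 = write_dataset(cfg, tmp_path / "run2")
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        a = write_dataset(small_config(seed=1), tmp_path / "a")
        b = write_dataset(small_config(seed=2), tmp_path / "b")
        assert a["utrs"].read_bytes() != b["utrs"].read_bytes()

    def test_emitted_files_are_consumable(self, tmp_path):
        cfg = small_config(seed=8)
        paths = write_dataset(cfg, tmp_path / "d")
        utrs = read_utr_fasta(paths["utrs"])
        assert len(utrs) == cfg.n_genes
        mrna = read_fc_table(paths["mrna"], "transcript")
        protein = read_fc_table(paths["protein"], "protein")
        assert len(mrna) == cfg.n_genes and len(protein) == cfg.n_genes
        ct = CtMatrix.from_csv(paths["ct_matrix"], paths["groups"])
        assert ct.values.shape == (cfg.n_mirnas, 2 * cfg.ct_n_per_group)
        truth = json.loads(paths["truth"].read_text())
        assert set(truth["target_genes"]) <= {u.gene_id for u in utrs}

    def test_prediction_sets_cover_targets_noisily(self):
        cfg = small_config(seed=10)
        rng = cfg.rng()
        _, truth = simulate_utrs(cfg, rng)
        simulate_overexpression(cfg, truth, rng)
        sets = simulate_prediction_sets(cfg, truth, rng)
        assert set(sets) == set(cfg.algorithms)
        targets = set(truth.target_genes)
        for members in sets.values():
            assert members & targets  # recovers some truth
            assert members - targets  # and adds background noise


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=10, n_targets=11)
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(utr_length=(10, 5))
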