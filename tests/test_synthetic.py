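import math

import numpy as np
import pytest

from strainkit.composition import gc_content
from strainkit.synthetic import (
    ConfigError,
    CrisprSpec,
    SimulationConfig,
    generate_strain_set,
    plant_crispr_array,
    plant_hgt_genes,
    simulate,
)
from .oracles import hamming_identity_percent


def _config(**kw):
    base = dict(
        n_strains=2,
        genome_length=60_000,
        genes_per_category={"Q": 20},
        per_category_divergence={"Q": 0.10},
        backbone_divergence=0.05,
        n_hgt_genes=0,
        crispr_specs=[],
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateStrainSet:
    def test_zero_divergence_gives_identical_strains(self):
        cfg = _config(per_category_divergence={"Q": 0.0}, backbone_divergence=0.0,
                      divergence_16s=0.0)
        genomes, _, _, _ = generate_strain_set(cfg)
        assert genomes[0].contigs[0][1] == genomes[1].contigs[0][1]

    def test_category_mismatch_fraction_within_binomial_bounds(self):
        # 50 genes x 900 bp at rate 0.10: the observed mismatch fraction
        # between ancestor and derived strain must sit within 3 binomial
        # standard deviations of the planted rate.
        rate = 0.10
        cfg = _config(genome_length=120_000, genes_per_category={"Q": 50},
                      per_category_divergence={"Q": rate}, seed=5)
        genomes, genes, _, _ = generate_strain_set(cfg)
        seq0 = genomes[0].contigs[0][1]
        seq1 = genomes[1].contigs[0][1]
        mismatches = total = 0
        for g in genes:
            if g.genome_id != genomes[0].genome_id or g.feature_type != "cds":
                continue
            a, b = seq0[g.start:g.end], seq1[g.start:g.end]
            mismatches += sum(1 for x, y in zip(a, b) if x != y)
            total += len(a)
        observed = mismatches / total
        sd = math.sqrt(rate * (1 - rate) / total)
        assert abs(observed - rate) <= 3 * sd

    def test_determinism_and_seed_sensitivity(self):
        a1 = generate_strain_set(_config(seed=1))[0]
        a2 = generate_strain_set(_config(seed=1))[0]
        b = generate_strain_set(_config(seed=2))[0]
        assert [g.contigs for g in a1] == [g.contigs for g in a2]
        assert a1[1].contigs != b[1].contigs

    def test_ancestor_gc_near_target(self):
        for seed in (0, 3):
            cfg = _config(gc_target=0.385, genome_length=120_000, seed=seed)
            genomes, _, _, _ = generate_strain_set(cfg)
            assert abs(gc_content(genomes[0]) / 100 - 0.385) <= 0.01

    def test_pairwise_identity_matches_independent_lineage_formula(self):
        # two derived strains both at rate p: expected per-site identity
        # is (1-p)^2 + p^2/3
        p = 0.10
        cfg = _config(n_strains=3, genome_length=150_000,
                      genes_per_category={"Q": 60}, per_category_divergence={"Q": p},
                      seed=9)
        genomes, genes, _, truth = generate_strain_set(cfg)
        expected = truth.expected_identity[("S02", "S03")]["Q"]
        assert expected == pytest.approx(100 * ((1 - p) ** 2 + p ** 2 / 3))
        seq1 = genomes[1].contigs[0][1]
        seq2 = genomes[2].contigs[0][1]
        idents, total = 0, 0
        for g in genes:
            if g.genome_id == genomes[0].genome_id and g.feature_type == "cds":
                total += g.end - g.start
                idents += sum(1 for x, y in zip(seq1[g.start:g.end], seq2[g.start:g.end])
                              if x == y)
        sd = 100 * math.sqrt(0.2 * 0.8 / total)
        assert abs(100 * idents / total - expected) <= 4 * sd

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            _config(n_strains=1).validate()
        with pytest.raises(ConfigError):
            _config(per_category_divergence={"Q": 0.9}).validate()
        with pytest.raises(ConfigError):
            _config(genome_length=10_000, genes_per_category={"Q": 20}).validate()
        with pytest.raises(ConfigError):
            CrisprSpec(dr_length=10).validate()
        with pytest.raises(ConfigError):
            CrisprSpec(dr_length=30, spacer_min=1, spacer_max=5).validate()


class TestPlanting:
    def test_no_hgt_requested_changes_nothing(self):
        cfg = _config()
        genomes, genes, _, truth = generate_strain_set(cfg)
        before = [g.contigs for g in genomes]
        updated, db = plant_hgt_genes(genomes, genes, cfg, truth=truth)
        assert len(updated) == len(genes)
        assert truth.hgt_genes == {}
        assert [g.contigs for g in genomes] == before
        # native genes still get focal-order database homologs
        assert any(lab.order == cfg.focal_order for lab in db.taxonomy.values())

    def test_planted_genes_are_composition_shifted_and_recorded(self):
        cfg = _config(n_hgt_genes=5)
        genomes, genes, _, truth = generate_strain_set(cfg)
        updated, db = plant_hgt_genes(genomes, genes, cfg, truth=truth)
        planted = [g for g in updated if g.gene_id in truth.hgt_genes]
        assert len(planted) == 5
        for g in planted:
            assert abs(gc_content(g.cds) / 100 - cfg.gc_target) >= 0.10
            donor_entry = f"db_{g.gene_id}_donor"
            assert db.taxonomy[donor_entry].order == truth.hgt_genes[g.gene_id]
            assert db.taxonomy[donor_entry].order != cfg.focal_order
            # the planted CDS really sits in the emitted genome
            seq = genomes[0].sequence(g.contig_id)
            assert seq[g.start:g.end] == g.cds

    def test_crispr_block_arithmetic(self):
        cfg = _config()
        genomes, genes, _, truth = generate_strain_set(cfg)
        rng = np.random.default_rng(4)
        spec = CrisprSpec(dr_length=30, n_spacers=3, spacer_min=36, spacer_max=37)
        entry = plant_crispr_array(genomes, genomes[0].genome_id, spec, rng,
                                   avoid=genes, truth=truth)
        assert entry.end - entry.start == 4 * 30 + sum(entry.spacer_lengths)
        seq = genomes[0].sequence(entry.contig_id)
        block = seq[entry.start:entry.end]
        assert block.startswith(entry.dr_consensus)
        assert block.endswith(entry.dr_consensus)
        assert truth.crisprs[-1] is entry

    def test_planted_spacers_distinct(self):
        cfg = _config()
        genomes, genes, _, _ = generate_strain_set(cfg)
        rng = np.random.default_rng(4)
        spec = CrisprSpec(dr_length=23, n_spacers=8, spacer_min=20, spacer_max=40)
        entry = plant_crispr_array(genomes, genomes[0].genome_id, spec, rng, avoid=genes)
        seq = genomes[0].sequence(entry.contig_id)
        starts = [entry.start]
        spacers = []
        pos = entry.start + entry.dr_length
        for length in entry.spacer_lengths:
            spacers.append(seq[pos:pos + length])
            pos += length + entry.dr_length
        assert len(set(spacers)) == len(spacers)


class TestFullScenario:
    def test_default_scenario_is_deterministic(self, default_scenario):
        again = simulate(SimulationConfig(seed=0))
        assert [g.contigs for g in again.genomes] == \
            [g.contigs for g in default_scenario.genomes]
        assert again.truth.hgt_genes == default_scenario.truth.hgt_genes

    def test_truth_elements_have_valid_coordinates(self, default_scenario):
        genomes = {g.genome_id: g for g in default_scenario.genomes}
        for c in default_scenario.truth.crisprs:
            seq = genomes[c.genome_id].sequence(c.contig_id)
            assert 0 <= c.start < c.end <= len(seq)
        gene_ids = {g.gene_id for g in default_scenario.genes}
        assert set(default_scenario.truth.hgt_genes) <= gene_ids

    def test_expected_identity_close_to_observed_whole_category(self, default_scenario):
        genomes = {g.genome_id: g for g in default_scenario.genomes}
        truth = default_scenario.truth
        for cat, rate in truth.per_category_divergence.items():
            seqs = []
            for sid in ("S02", "S03"):
                parts = []
                for g in default_scenario.genes:
                    if g.genome_id == sid and g.category == cat \
                            and not g.gene_id.endswith("16S") and "hgt" not in g.gene_id:
                        parts.append(genomes[sid].sequence(g.contig_id)[g.start:g.end])
                seqs.append("".join(parts))
            observed = hamming_identity_percent(seqs[0], seqs[1])
            expected = truth.expected_identity[("S02", "S03")][cat]
            assert observed == pytest.approx(expected, abs=1.5)
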