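"""Ground-truth generator: determinism, construction invariants, models."""

import json

import numpy as np
import pytest
from scipy import stats

from methylbloom.association import correlate
from methylbloom.codon_recoding import translate
from methylbloom.sequence_context import read_fasta, read_gene_models, spliced_cds
from methylbloom.synthetic_data import (
    SimulatedStudy,
    SimulationConfig,
    apply_azaC,
    generate_genome,
    generate_methylomes,
    generate_study,
    simulate_bisulfite_clones,
)

TINY = dict(n_accessions=4, n_genes=3, n_causal=1, cds_codons_range=(60, 80))


class TestGenerateGenome:
    def test_seed_determinism_bytes(self, tmp_path):
        for run in ("a", "b"):
            generate_genome(SimulationConfig(seed=7, n_genes=2, n_causal=1)).write(tmp_path / run)
        for name in ("genome.fasta", "genes.gff3"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_every_cds_translates_cleanly(self):
        genome = generate_genome(SimulationConfig(seed=1, n_genes=8, n_causal=2))
        for gene in genome.genes:
            cds = spliced_cds(gene, genome.sequences[gene.region.chrom])
            protein = translate(cds)  # raises on internal stops
            assert protein.startswith("M") and protein.endswith("*")

    def test_gff_round_trip_through_reader(self, tmp_path):
        genome = generate_genome(SimulationConfig(seed=3, n_genes=5, n_causal=2))
        genome.write(tmp_path)
        loaded = read_gene_models(tmp_path / "genes.gff3")
        by_id = {g.gene_id: g for g in loaded}
        assert len(loaded) == 5
        for gene in genome.genes:
            back = by_id[gene.gene_id]
            assert back.region == gene.region
            assert back.atg_pos == gene.atg_pos
            assert back.cds_segments == gene.cds_segments
        sequences = read_fasta(tmp_path / "genome.fasta")
        assert sequences == genome.sequences

    def test_promoters_fit_between_genes(self):
        from methylbloom.sequence_context import promoter_region

        genome = generate_genome(SimulationConfig(seed=2, n_genes=6, n_causal=2))
        for gene in genome.genes:
            window = promoter_region(
                gene, len(genome.sequences[gene.region.chrom])
            ).region
            for other in genome.genes:
                if other.region.chrom != window.chrom:
                    continue
                overlap = max(
                    0, min(window.end, other.region.end) - max(window.start, other.region.start)
                )
                assert overlap == 0


class TestGenerateMethylomes:
    def test_full_determinism(self, tmp_path):
        for run in ("a", "b"):
            generate_study(SimulationConfig(seed=11, **TINY)).write(tmp_path / run)
        for rel in ("truth.json", "phenotype.csv", "methylomes/acc01.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_noise_free_single_causal_gene_has_rho_one(self):
        config = SimulationConfig(
            seed=5, n_accessions=10, n_genes=4, n_causal=1, phenotype_sd=0.0,
            cds_codons_range=(150, 200),
        )
        study = generate_study(config, materialize=False)
        gene = study.causal_genes[0]
        res = correlate(study.mc_matrix[gene], study.phenotype["flowering_days"])
        assert res.coefficient == pytest.approx(1.0)

    def test_null_effect_leaves_phenotype_uncoupled(self):
        """With zero effect size the mean causal-gene correlation vanishes."""
        rs = []
        for seed in range(40):
            config = SimulationConfig(
                seed=seed, n_accessions=12, n_genes=3, n_causal=1,
                effect_days_per_site=0.0, cds_codons_range=(60, 80),
            )
            study = generate_study(config, materialize=False)
            r = stats.spearmanr(
                study.mc_matrix[study.causal_genes[0]],
                study.phenotype["flowering_days"],
            )[0]
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_truth_json_is_sufficient_for_downstream_checks(self, small_study, tmp_path):
        small_study.write(tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        mc = truth["mc"]
        for accession in small_study.accessions:
            for gene_id in small_study.mc_matrix.columns:
                assert mc[accession][gene_id] == int(
                    small_study.mc_matrix.loc[accession, gene_id]
                )
        assert truth["causal_genes"] == small_study.causal_genes
        assert set(truth["flowering_days"]) == set(small_study.accessions)

    def test_expression_negatively_coupled_to_methylation(self, small_study):
        gene = small_study.causal_genes[0]
        r = stats.spearmanr(
            small_study.expression[gene], small_study.mc_matrix[gene]
        )[0]
        assert r < 0


class TestApplyAzaC:
    def _study(self, seed=9):
        return generate_study(SimulationConfig(seed=seed, **TINY))

    def test_zero_reduction_is_identity(self):
        study = self._study()
        config = SimulationConfig(seed=1, azaC_reduction_range=(0.0, 0.0), **TINY)
        records = study.methylomes[study.accessions[0]]
        perturbed, realized = apply_azaC(records, study.genome.genes, config)
        assert perturbed == records
        assert all(f == 0 for f in realized.values())

    def test_full_reduction_erases_gene_body_methylation(self):
        study = self._study()
        config = SimulationConfig(seed=1, azaC_reduction_range=(1.0, 1.0), **TINY)
        records = study.methylomes[study.accessions[0]]
        perturbed, realized = apply_azaC(records, study.genome.genes, config)
        for gene in study.genome.genes:
            region = gene.region
            left = [
                r for r in perturbed
                if r.chrom == region.chrom and region.contains(r.pos) and r.methylated
            ]
            assert left == []

    def test_realized_reduction_within_configured_range(self):
        config = SimulationConfig(seed=13, n_accessions=1, n_genes=12, n_causal=6)
        study = generate_study(config)
        records = study.methylomes[study.accessions[0]]
        _, realized = apply_azaC(records, study.genome.genes, config)
        fractions = [f for f in realized.values() if f > 0]
        assert fractions, "expected methylated genes to perturb"
        assert all(0.14 <= f <= 0.56 for f in fractions)

    def test_mean_reduction_near_uniform_mean(self):
        # many genes: mean realized fraction approaches (0.14 + 0.56) / 2
        config = SimulationConfig(seed=17, n_accessions=1, n_genes=60, n_causal=1)
        study = generate_study(config)
        records = study.methylomes[study.accessions[0]]
        _, realized = apply_azaC(records, study.genome.genes, config)
        fractions = [f for f in realized.values() if f > 0]
        assert np.mean(fractions) == pytest.approx(0.35, abs=0.03)


class TestSimulateClones:
    def _config(self, **kw):
        base = dict(seed=23, n_clones=10, sequencing_error=0.0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_fully_methylated_clones_identical_to_reference(self, rng):
        reference = "ACGTCCGGAC"
        probs = {i: 1.0 for i, b in enumerate(reference) if b == "C"}
        clones = simulate_bisulfite_clones(reference, probs, self._config(), rng)
        assert all(c == reference for c in clones)

    def test_unmethylated_full_conversion_turns_every_c_to_t(self, rng):
        reference = "ACGTCCGGAC"
        probs = {i: 0.0 for i, b in enumerate(reference) if b == "C"}
        config = self._config(conversion_efficiency=1.0)
        clones = simulate_bisulfite_clones(reference, probs, config, rng)
        expected = reference.replace("C", "T")
        assert all(c == expected for c in clones)

    def test_retention_rate_matches_closed_form(self, rng):
        """retention prob = p + (1 - p)(1 - efficiency)."""
        reference = "AC" * 50
        p, eff = 0.7, 0.99
        probs = {i: p for i, b in enumerate(reference) if b == "C"}
        config = self._config(n_clones=1000, conversion_efficiency=eff)
        clones = simulate_bisulfite_clones(reference, probs, config, rng)
        c_positions = [i for i, b in enumerate(reference) if b == "C"]
        retained = sum(c[i] == "C" for c in clones for i in c_positions)
        total = len(clones) * len(c_positions)
        expected = p + (1 - p) * (1 - eff)
        # 99% envelope on the binomial proportion
        half_width = 2.576 * np.sqrt(expected * (1 - expected) / total)
        assert abs(retained / total - expected) < half_width

    def test_missing_probability_rejected(self, rng):
        with pytest.raises(ValueError, match="probability"):
            simulate_bisulfite_clones("ACGT", {}, self._config(), rng)

    def test_sequencing_error_produces_ambiguous_bases(self, rng):
        reference = "A" * 2000
        config = self._config(n_clones=5, sequencing_error=0.01)
        clones = simulate_bisulfite_clones(reference, {}, config, rng)
        changed = sum(b != "A" for c in clones for b in c)
        assert 0 < changed < 1000
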