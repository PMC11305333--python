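"""Generator contracts: seeded determinism, construction guarantees, and the
Mendelian/mapping expectations the analysis stages later rely on."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from convloss import io, lof, simulate
from convloss.models import CapacityError, EffectClass, revcomp
from convloss.segregation import chisq_gof


class TestGenome:
    def test_seeded_determinism(self):
        g1 = simulate.gen_genome(1, 100_000, seed=1)
        g2 = simulate.gen_genome(1, 100_000, seed=1)
        assert g1.seqs == g2.seqs
        assert g1.seqs != simulate.gen_genome(1, 100_000, seed=2).seqs

    def test_shape_contract(self):
        g = simulate.gen_genome(2, 50_000, seed=7)
        assert g.chroms == ["chr1", "chr2"]
        assert all(length == 50_000 for length in g.lengths.values())

    def test_uniform_base_composition(self):
        # binomial bounds at p=0.25: at n=100k a frequency outside
        # [0.22, 0.28] is >20 sigma away
        g = simulate.gen_genome(1, 100_000, seed=3)
        seq = g.seqs["chr1"]
        for base in "ACGT":
            assert 0.22 <= seq.count(base) / len(seq) <= 0.28

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            simulate.gen_genome(1, 5_000, seed=1)
        with pytest.raises(ValueError):
            simulate.gen_genome(0, 50_000, seed=1)


class TestGeneModels:
    def test_splice_sites_and_orf(self, small_genome_annotation):
        """Every intron is GT..AG on the coding strand; every CDS is a clean ORF."""
        genome, annotation = small_genome_annotation
        strands = set()
        for gene in annotation:
            strands.add(gene.strand)
            seq = genome.seqs[gene.chrom]
            for s, e in gene.introns:
                intron = seq[s:e] if gene.strand == "+" else revcomp(seq[s:e])
                assert intron[:2] == "GT" and intron[-2:] == "AG"
            _, protein = lof.splice_and_translate(gene, genome, [])
            cds_seq = "".join(
                seq[s:e] for s, e in gene.cds
            )
            if gene.strand == "-":
                cds_seq = revcomp(cds_seq)
            full = str(Seq(cds_seq).translate())
            assert full.startswith("M")
            assert full.endswith("*") and full.count("*") == 1
            assert protein == full[:-1]
        assert strands == {"+", "-"}

    def test_requested_exon_count(self):
        genome = simulate.gen_genome(1, 60_000, seed=5)
        ann = simulate.gen_gene_models(genome, 1, exon_count_range=(7, 7), seed=6)
        gene = ann.genes[0]
        assert len(gene.exons) == 7 and gene.n_introns == 6

    def test_gff3_round_trip(self, small_genome_annotation, tmp_path):
        _, annotation = small_genome_annotation
        path = tmp_path / "genes.gff3"
        io.write_gff3(annotation, path, seed=1)
        back = io.read_gff3(path)
        assert len(back) == len(annotation)
        for orig in annotation:
            echo = back.by_id(orig.gene_id)
            assert echo.exons == orig.exons
            assert echo.cds == orig.cds
            assert echo.strand == orig.strand

    def test_capacity_error(self):
        genome = simulate.gen_genome(1, 12_000, seed=1)
        with pytest.raises(CapacityError):
            simulate.gen_gene_models(genome, 50, seed=2)


class TestInjectVariants:
    def test_class_construction_contracts(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        spec = [("frameshift_indel", 3), ("synonymous", 5), ("inframe_indel", 3)]
        variants, truth = simulate.inject_variants(genome, annotation, spec, seed=31)
        by_id = {vid: cls for vid, cls, _ in truth.variant_truth}
        for var in variants:
            cls = by_id[var.variant_id]
            if cls is EffectClass.FRAMESHIFT:
                assert abs(var.net_length) % 3 != 0
            elif cls is EffectClass.INFRAME_INDEL:
                assert var.net_length % 3 == 0
            elif cls is EffectClass.SYNONYMOUS:
                assert var.is_snv
                gene = annotation.locate(var.chrom, var.pos0)
                call = lof.classify_variant(gene, var, genome)
                assert call.effect_class is EffectClass.SYNONYMOUS

    def test_exact_large_deletion_inside_exon(self, big_exon_gene):
        """A 474-bp deletion lands entirely inside one coding exon."""
        genome, annotation = big_exon_gene
        variants, truth = simulate.inject_variants(
            genome, annotation, [("large_exonic_deletion", 1)], seed=33,
            large_del_length=474,
        )
        assert len(variants) == 1 and not truth.skipped
        var = variants[0]
        assert len(var.ref) - len(var.alt) == 474
        gene = annotation.locate(var.chrom, var.pos0)
        span = (var.pos0 + 1, var.pos0 + len(var.ref))
        assert any(s <= span[0] and span[1] <= e for s, e in gene.cds)

    def test_impossible_class_skipped_with_note(self):
        genome = simulate.gen_genome(1, 30_000, seed=41)
        ann = simulate.gen_gene_models(genome, 1, exon_count_range=(1, 1), seed=42)
        variants, truth = simulate.inject_variants(
            genome, ann, [("splice_donor", 2)], seed=43
        )
        assert variants == []
        assert len(truth.skipped) == 2

    def test_truth_table_complete_and_deterministic(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        spec = [("missense", 4), ("intronic", 3)]
        v1, t1 = simulate.inject_variants(genome, annotation, spec, seed=44)
        v2, t2 = simulate.inject_variants(genome, annotation, spec, seed=44)
        assert v1 == v2
        assert {v.variant_id for v in v1} == {vid for vid, _, _ in t1.variant_truth}
        assert t1.variant_truth == t2.variant_truth


class TestF2Population:
    def test_single_recessive_ratio(self):
        pop = simulate.gen_f2_population("single_recessive", 10_000, seed=51)
        frac = (pop["phenotype"] == "trait_absent").mean()
        assert abs(frac - 0.25) < 0.02

    def test_duplicate_recessive_ratio_matches_enumeration(self):
        """Mutant fraction equals the 9-class two-locus enumeration (7/16)."""
        expected = sum(
            pa * pb
            for ga, pa in zip(range(3), (0.25, 0.5, 0.25))
            for gb, pb in zip(range(3), (0.25, 0.5, 0.25))
            if ga == 2 or gb == 2
        )
        assert expected == pytest.approx(7 / 16)
        pop = simulate.gen_f2_population("duplicate_recessive", 10_000, seed=52)
        frac = (pop["phenotype"] == "trait_absent").mean()
        assert abs(frac - expected) < 0.02

    def test_full_penetrance_means_causal_homozygosity(self):
        pop = simulate.gen_f2_population("duplicate_recessive", 3_000, seed=53)
        mutants = pop[pop["phenotype"] == "trait_absent"]
        assert (
            (mutants["geno_pl"] == "hom_alt") | (mutants["geno_pl2"] == "hom_alt")
        ).all()

    def test_penetrance_thins_mutants(self):
        pop = simulate.gen_f2_population(
            "single_recessive", 10_000, penetrance=0.5, seed=54
        )
        frac = (pop["phenotype"] == "trait_absent").mean()
        assert abs(frac - 0.125) < 0.02

    def test_distortion_depletes_hom_alt(self):
        pop = simulate.gen_f2_population("single_recessive", 10_000, distortion=0.5, seed=55)
        counts = pop["geno_pl"].value_counts()
        assert counts["hom_alt"] < 0.8 * counts["hom_ref"]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_f2_population("dominant", 10, seed=1)

    def test_genotype_ratio_121_calibrated_across_seeds(self):
        """Per-seed 1:2:1 chi-square rejections at alpha=0.01 stay at the
        nominal rate (exact binomial bound: >7/100 failures has probability
        ~1e-5 for a true 1:2:1 generator), and the pooled counts over all
        seeds fit 1:2:1."""
        failures = 0
        pooled = np.zeros(3)
        for seed in range(100):
            pop = simulate.gen_f2_population("single_recessive", 10_000, seed=seed)
            counts = pop["geno_pl"].value_counts()
            obs = np.array([counts.get(g, 0) for g in ("hom_ref", "het", "hom_alt")])
            pooled += obs
            if chisq_gof(obs, (1, 2, 1)).p <= 0.01:
                failures += 1
        assert failures <= 7
        assert chisq_gof(pooled, (1, 2, 1)).p > 1e-4


class TestBsaCounts:
    def test_expected_delta_matches_analytic_curve(self):
        """Monte-Carlo delta matches the analytic sampling-model expectation
        E[delta] = 2/3 - (4/3) r at every marker: 2/3 at the QTL (r=0),
        0 for unlinked markers (r=1/2)."""
        counts, truth = simulate.gen_bsa_counts(
            chrom_len=10_000_000, qtl_position=5_000_000,
            n_high_bulk=200, n_low_bulk=200, depth=10_000, n_snps=400,
            map_rate=40.0, seed=61,
        )
        idx_h = counts["alt_depth_high"] / (counts["alt_depth_high"] + counts["ref_depth_high"])
        idx_l = counts["alt_depth_low"] / (counts["alt_depth_low"] + counts["ref_depth_low"])
        delta = idx_h - idx_l
        r = simulate.haldane_r((counts["pos"] - truth.qtl_position).abs() / 1e6 * 40.0)
        expected = 2 / 3 - 4 / 3 * r
        assert np.abs(delta - expected).mean() < 0.05
        near = delta[(counts["pos"] - truth.qtl_position).abs() < 50_000]
        assert abs(near.mean() - 2 / 3) < 0.05
        far = delta[r > 0.47]
        assert len(far) > 30 and abs(far.mean()) < 0.05

    def test_seeded_reproducibility_and_bounds(self):
        c1, _ = simulate.gen_bsa_counts(1_000_000, 500_000, n_snps=50, seed=62)
        c2, _ = simulate.gen_bsa_counts(1_000_000, 500_000, n_snps=50, seed=62)
        pd.testing.assert_frame_equal(c1, c2)
        with pytest.raises(ValueError):
            simulate.gen_bsa_counts(1_000_000, 2_000_000, seed=1)

    def test_haldane_transform(self):
        assert simulate.haldane_r(0.0) == 0.0
        assert simulate.haldane_r(1e9) == pytest.approx(0.5)
        assert simulate.haldane_r(50.0) == pytest.approx((1 - np.exp(-1)) / 2)


class TestExpressionPair:
    def test_perfect_conservation_rank_correlation(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes_per_species=40, n_samples=60, n_modules=4, rho=1.0,
            noise_sd=0.0, seed=71,
        )
        pair, orthology, truth = simulate.gen_expression_pair(cfg)
        from scipy.stats import spearmanr

        modules = truth.extras["modules_a"]
        genes = list(pair.expr_a.index)
        same = [
            (a, b) for a in genes[:10] for b in genes[:10]
            if a < b and modules[a] == modules[b]
        ]
        assert same
        for a, b in same:
            rho, _ = spearmanr(pair.expr_a.loc[a], pair.expr_a.loc[b])
            assert abs(rho) > 0.999

    def test_zero_rho_module_agreement_at_chance(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes_per_species=400, n_samples=10, n_modules=8, rho=0.0, seed=72
        )
        pair, orthology, truth = simulate.gen_expression_pair(cfg)
        ma, mb = truth.extras["modules_a"], truth.extras["modules_b"]
        agree = np.mean(
            [ma[a] == mb[b] for a, b in zip(orthology["gene_a"], orthology["gene_b"])]
        )
        # rho=0 forces reassignment to a different module: below chance 1/8
        assert agree < 1 / 8

    def test_shape_and_finiteness(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes_per_species=30, n_samples=20, n_modules=5, paralog_rate=0.2, seed=73
        )
        pair, orthology, _ = simulate.gen_expression_pair(cfg)
        assert pair.expr_a.shape == (30, 20)
        assert pair.expr_b.shape == (36, 20)
        assert np.isfinite(pair.expr_a.to_numpy()).all()
        assert (pair.expr_a.to_numpy() >= 0).all()
        assert len(orthology) == 36

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_expression_pair(
                simulate.ExpressionSimConfig(n_modules=0, rho=0.5)
            )
        with pytest.raises(ValueError):
            simulate.gen_expression_pair(simulate.ExpressionSimConfig(rho=1.5))


class TestTreeWithLosses:
    def test_zero_losses_all_present(self):
        _, traits, _ = simulate.gen_tree_with_losses(12, 0, seed=81)
        assert set(traits.values()) == {1}

    @pytest.mark.parametrize("n_losses", [1, 3, 6])
    def test_dollo_recovers_planted_count(self, n_losses):
        from convloss.comparative import min_independent_origins

        tree, traits, truth = simulate.gen_tree_with_losses(20, n_losses, seed=82)
        assert truth.loss_events == n_losses
        assert min_independent_origins(tree, traits, "dollo_loss") == n_losses

    def test_newick_round_trip(self, tmp_path):
        tree, traits, _ = simulate.gen_tree_with_losses(10, 2, seed=83)
        path = tmp_path / "tree.nwk"
        io.write_newick(tree, path)
        back = io.read_newick(path)
        orig_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
        back_taxa = {lf.taxon.label for lf in back.leaf_node_iter()}
        assert back_taxa == orig_taxa == set(traits)

    def test_infeasible_count_rejected(self):
        with pytest.raises(Exception):
            simulate.gen_tree_with_losses(5, 10, seed=1)
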