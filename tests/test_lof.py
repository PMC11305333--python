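"""Classification cascade vs the translate-the-mutant oracle, plus the
strand-symmetry and totality guarantees."""

import pytest

from convloss import lof, simulate
from convloss.models import EffectClass, Genome, GeneModel, VariantRecord, revcomp


def _first_gene_with_intron(annotation, min_introns=1):
    for gene in annotation:
        if gene.n_introns >= min_introns:
            return gene
    raise AssertionError("no intronful gene in fixture")


class TestSpliceAndTranslate:
    def test_no_variants_identity(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        for gene in annotation:
            _, p1 = lof.splice_and_translate(gene, genome, [])
            _, p2 = lof.splice_and_translate(gene, genome, [])
            assert p1 == p2 and p1.startswith("M") and "*" not in p1

    def test_single_bp_insertion_diverges_protein(self, small_genome_annotation):
        """A 1-bp CDS insertion changes the protein at/after the insertion codon."""
        genome, annotation = small_genome_annotation
        variants, truth = simulate.inject_variants(
            genome, annotation, [("frameshift_indel", 10)], seed=7
        )
        checked = 0
        for var in variants:
            if var.net_length != 1:
                continue
            gene = annotation.locate(var.chrom, var.pos0)
            _, wt = lof.splice_and_translate(gene, genome, [])
            _, mut = lof.splice_and_translate(gene, genome, [var])
            assert mut != wt
            tx = gene.tx_cds_index(var.pos0)
            codon = tx // 3
            assert mut[:max(0, codon - 1)] == wt[:max(0, codon - 1)]
            checked += 1
        assert checked >= 2

    def test_reverse_strand_protein_matches_mirror_construction(self):
        """A minus-strand gene translates identically to its reverse-complement
        mirror built as a plus-strand gene."""
        genome = simulate.gen_genome(1, 60_000, seed=9)
        ann = simulate.gen_gene_models(genome, 2, seed=10)
        gene = next(g for g in ann if g.strand == "-")
        L = len(genome.seqs[gene.chrom])
        mirror_genome = Genome({gene.chrom: revcomp(genome.seqs[gene.chrom])})
        mirror = GeneModel(
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand="+",
            exons=sorted((L - e, L - s) for s, e in gene.exons),
            cds=sorted((L - e, L - s) for s, e in gene.cds),
        )
        _, p_minus = lof.splice_and_translate(gene, genome, [])
        _, p_plus = lof.splice_and_translate(mirror, mirror_genome, [])
        assert p_minus == p_plus

    def test_ref_mismatch_is_hard_error(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        gene = annotation.genes[0]
        pos0 = gene.cds[0][0] + 4
        actual = genome.seqs[gene.chrom][pos0]
        wrong = "A" if actual != "A" else "C"
        other = "G" if wrong != "G" else "T"
        var = VariantRecord(gene.chrom, pos0 + 1, wrong, other, "bad")
        with pytest.raises(ValueError, match=str(pos0 + 1)):
            lof.splice_and_translate(gene, genome, [var])


class TestClassifyVariant:
    def test_474bp_inframe_exonic_deletion_is_lof(self, big_exon_gene):
        """474 mod 3 = 0, yet the deletion is LOF by the coding-bp threshold."""
        genome, annotation = big_exon_gene
        variants, _ = simulate.inject_variants(
            genome, annotation, [("large_exonic_deletion", 1)], seed=13,
            large_del_length=474,
        )
        var = variants[0]
        gene = annotation.locate(var.chrom, var.pos0)
        call = lof.classify_variant(gene, var, genome)
        assert call.effect_class is EffectClass.LARGE_EXONIC_DELETION
        assert call.lof_flag
        # and the oracle agrees: 158 codons gone
        _, wt = lof.splice_and_translate(gene, genome, [])
        _, mut = lof.splice_and_translate(gene, genome, [var])
        assert len(mut) <= len(wt) - 158

    def test_donor_plus_one_snv_is_lof(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        gene = _first_gene_with_intron(annotation)
        _, donor, _ = next(gene.splice_windows())
        pos0 = donor[0]
        ref = genome.seqs[gene.chrom][pos0]
        alt = "A" if ref != "A" else "C"
        call = lof.classify_variant(
            gene, VariantRecord(gene.chrom, pos0 + 1, ref, alt, "d1"), genome
        )
        assert call.effect_class is EffectClass.SPLICE_DONOR
        assert call.lof_flag

    def test_cascade_matches_generator_intent(self, small_genome_annotation):
        """Every injectable class classifies back to its intended label."""
        genome, annotation = small_genome_annotation
        spec = [
            ("splice_donor", 4), ("splice_acceptor", 4), ("frameshift_indel", 6),
            ("stop_gained", 5), ("inframe_indel", 4), ("missense", 5),
            ("synonymous", 5), ("intronic", 4), ("intergenic", 4),
        ]
        variants, truth = simulate.inject_variants(genome, annotation, spec, seed=14)
        intended = {vid: cls for vid, cls, _ in truth.variant_truth}
        for var in variants:
            gene = annotation.locate(var.chrom, var.pos0, lof.GENE_FLANK)
            call = lof.classify_variant(gene, var, genome)
            assert call.effect_class is intended[var.variant_id], var.variant_id

    def test_stop_gained_truncation_rule(self, small_genome_annotation):
        """A premature stop in the last codons truncates <10% and is not LOF."""
        genome, annotation = small_genome_annotation
        from convloss.models import STOP_CODONS

        found = False
        for gene in annotation:
            n_aa = gene.n_codons - 1
            for c in range(n_aa - max(1, int(0.05 * n_aa)), n_aa):
                codon, gpos = gene.codon(genome, c)
                if codon in STOP_CODONS:
                    continue
                for off in range(3):
                    for b in "ACGT":
                        if b == codon[off]:
                            continue
                        if codon[:off] + b + codon[off + 1:] in STOP_CODONS:
                            base = b if gene.strand == "+" else revcomp(b)
                            ref = genome.seqs[gene.chrom][gpos[off]]
                            var = VariantRecord(gene.chrom, gpos[off] + 1, ref, base, "s1")
                            call = lof.classify_variant(gene, var, genome)
                            assert call.effect_class is EffectClass.STOP_GAINED
                            assert call.truncation_fraction < 0.1
                            assert not call.lof_flag
                            found = True
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                break
        assert found

    def test_strand_invariance_of_classification(self, small_genome_annotation):
        """Classifying against the reverse-complement mirror construction
        yields the identical effect class."""
        genome, annotation = small_genome_annotation
        spec = [("missense", 3), ("synonymous", 3), ("splice_donor", 3), ("stop_gained", 3)]
        variants, _ = simulate.inject_variants(genome, annotation, spec, seed=15)
        for var in variants:
            gene = annotation.locate(var.chrom, var.pos0)
            direct = lof.classify_variant(gene, var, genome)
            L = len(genome.seqs[gene.chrom])
            mirror_genome = Genome({gene.chrom: revcomp(genome.seqs[gene.chrom])})
            mirror_gene = GeneModel(
                gene_id=gene.gene_id, chrom=gene.chrom,
                strand="-" if gene.strand == "+" else "+",
                exons=sorted((L - e, L - s) for s, e in gene.exons),
                cds=sorted((L - e, L - s) for s, e in gene.cds),
            )
            mirror_var = VariantRecord(
                var.chrom, L - var.pos0, revcomp(var.ref), revcomp(var.alt), var.variant_id
            )
            mirrored = lof.classify_variant(mirror_gene, mirror_var, mirror_genome)
            assert mirrored.effect_class is direct.effect_class
            assert mirrored.lof_flag == direct.lof_flag

    def test_totality_every_variant_gets_one_class(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        spec = [(name, 3) for name in (
            "splice_donor", "splice_acceptor", "frameshift_indel", "stop_gained",
            "inframe_indel", "missense", "synonymous", "intronic", "intergenic",
        )]
        variants, _ = simulate.inject_variants(genome, annotation, spec, seed=16)
        calls = lof.classify_all(annotation, variants, genome)
        assert len(calls) == len(variants)
        assert all(isinstance(c.effect_class, EffectClass) for c in calls)

    def test_multiallelic_and_symbolic_rejected(self, small_genome_annotation, tmp_path):
        # multi-allelic records are rejected at the record boundary ...
        with pytest.raises(ValueError):
            VariantRecord("chr1", 10, "A", "C,G", "m1")
        # ... and when read from VCF they must be split upstream
        from convloss import io

        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\tm1\tA\tC,G\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            io.read_vcf(vcf)

    def test_noncanonical_splice_site_not_auto_lof(self):
        """An annotated intron without GT/AG termini is flagged, never LOF."""
        genome = simulate.gen_genome(1, 60_000, seed=17)
        ann = simulate.gen_gene_models(genome, 1, seed=18)
        gene = ann.genes[0]
        s, e = gene.introns[0]
        # corrupt the donor dinucleotide in the genome sequence
        win = (s, s + 2) if gene.strand == "+" else (e - 2, e)
        old = genome.seqs[gene.chrom][win[0]:win[1]]
        genome.replace_segment(gene.chrom, win[0], win[1], "CC")
        pos0 = win[0]
        ref = genome.seqs[gene.chrom][pos0]
        alt = "G" if ref != "G" else "T"
        call = lof.classify_variant(
            gene, VariantRecord(gene.chrom, pos0 + 1, ref, alt, "nc1"), genome
        )
        assert "noncanonical_site" in call.note
        assert not call.lof_flag
        genome.replace_segment(gene.chrom, win[0], win[1], old)


class TestSimulateMissplice:
    def test_frame_disrupting_retention(self, small_genome_annotation):
        """A retained intron of length not divisible by 3 shifts the frame."""
        genome, annotation = small_genome_annotation
        for gene in annotation:
            for ti in range(gene.n_introns):
                gi = gene.intron_genomic_index(ti)
                ilen = gene.introns[gi][1] - gene.introns[gi][0]
                _, call = lof.simulate_missplice(gene, genome, ti)
                if ilen % 3 != 0:
                    assert call.effect_class is EffectClass.FRAMESHIFT
                else:
                    # stop-in-all-frames motif guarantees a premature stop
                    assert call.effect_class is EffectClass.STOP_GAINED

    def test_retained_intron_truncates_translation(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        gene = _first_gene_with_intron(annotation)
        _, wt = lof.splice_and_translate(gene, genome, [])
        transcript, call = lof.simulate_missplice(gene, genome, 0)
        assert call.truncation_fraction > 0
        gi = gene.intron_genomic_index(0)
        ilen = gene.introns[gi][1] - gene.introns[gi][0]
        _, spliced = lof.splice_and_translate(gene, genome, [])
        assert len(transcript) == sum(e - s for s, e in gene.exons) + ilen

    def test_intronless_gene_errors(self):
        genome = simulate.gen_genome(1, 30_000, seed=19)
        ann = simulate.gen_gene_models(genome, 1, exon_count_range=(1, 1), seed=20)
        with pytest.raises(ValueError):
            lof.simulate_missplice(ann.genes[0], genome, 0)

    def test_index_out_of_range(self, small_genome_annotation):
        genome, annotation = small_genome_annotation
        gene = _first_gene_with_intron(annotation)
        with pytest.raises(ValueError):
            lof.simulate_missplice(gene, genome, gene.n_introns)


class TestNormalization:
    def test_indels_left_aligned(self):
        """A deletion in a homopolymer shifts to its leftmost representation."""
        seq = "ACGT" + "A" * 10 + "CGTAGCTAG" + "C" * 20
        genome = Genome({"chrN": seq})
        # delete one A at the right end of the A-run (pos 1-based 13, ref 'AA' -> 'A')
        var = VariantRecord("chrN", 13, "AA", "A", "la1")
        norm = lof.normalize_variant(var, genome)
        assert norm.pos == 4  # anchored at the T before the A-run
        assert len(norm.ref) == 2 and len(norm.alt) == 1

    def test_shared_context_trimmed(self):
        genome = Genome({"chrN": "ACGTACGTACGT"})
        var = VariantRecord("chrN", 2, "CGT", "CAT", "tr1")
        norm = lof.normalize_variant(var, genome)
        assert (norm.pos, norm.ref, norm.alt) == (3, "G", "A")
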