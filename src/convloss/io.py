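"""Readers and writers for the standard formats the toolkit exchanges.

FASTA goes through Biopython, GFF3 reading through gffutils, VCF reading
through pysam, trees through dendropy; tables are pandas TSV.  Writers emit a
provenance comment (tool version, seed, parameters) wherever the format
allows comments.
"""

from __future__ import annotations

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .models import AnnotationSet, GeneModel, Genome, GenomeSequence, VariantRecord

_SOURCE = "convloss"


def _provenance(seed=None, **params) -> str:
    bits = [f"version={__version__}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits.extend(f"{k}={v}" for k, v in params.items())
    return f"{_SOURCE} " + " ".join(bits)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path, seed=None) -> None:
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.chrom_id, description=_provenance(seed))
        for rec in genome.records()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Genome:
    return Genome([GenomeSequence(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")])


# ---------------------------------------------------------------------------
# GFF3 (written 1-based inclusive)
# ---------------------------------------------------------------------------

def write_gff3(annotation: AnnotationSet, path, seed=None) -> None:
    lines = ["##gff-version 3", f"#!{_provenance(seed)}"]
    for gene in annotation:
        gs, ge = gene.span
        gid = gene.gene_id
        attrs = f"ID={gid}"
        lines.append(
            f"{gene.chrom}\t{_SOURCE}\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t{attrs}"
        )
        mid = f"{gid}.t1"
        lines.append(
            f"{gene.chrom}\t{_SOURCE}\tmRNA\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\tID={mid};Parent={gid}"
        )
        for i, (s, e) in enumerate(gene.exons, 1):
            lines.append(
                f"{gene.chrom}\t{_SOURCE}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={mid}.exon{i};Parent={mid}"
            )
        # phase: bases to remove from the segment start (transcription order)
        # to reach the next codon boundary
        segs = gene.cds if gene.strand == "+" else gene.cds[::-1]
        cum = 0
        phases = []
        for s, e in segs:
            phases.append((3 - cum % 3) % 3)
            cum += e - s
        if gene.strand == "-":
            phases = phases[::-1]
        for i, ((s, e), ph) in enumerate(zip(gene.cds, phases), 1):
            lines.append(
                f"{gene.chrom}\t{_SOURCE}\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t{ph}\t"
                f"ID={mid}.cds;Parent={mid}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> AnnotationSet:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(g, featuretype="CDS"))
        genes.append(
            GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand, exons=exons, cds=cds)
        )
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# VCF v4.2
# ---------------------------------------------------------------------------

def write_vcf(variants, path, genome: Genome | None = None, effects=None, seed=None) -> None:
    """Write variants; if ``effects`` (variant_id -> EffectCall) is given the
    INFO column carries ``CLE`` (class) and ``LOF`` (0/1) tags."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={_provenance(seed)}",
    ]
    if genome is not None:
        for chrom, length in genome.lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    else:
        for chrom in sorted({v.chrom for v in variants}):
            lines.append(f"##contig=<ID={chrom}>")
    if effects is not None:
        lines.append('##INFO=<ID=CLE,Number=1,Type=String,Description="Effect class">')
        lines.append('##INFO=<ID=LOF,Number=1,Type=Integer,Description="Loss of function flag">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        info = "."
        if effects is not None and v.variant_id in effects:
            call = effects[v.variant_id]
            info = f"CLE={call.effect_class.value};LOF={int(call.lof_flag)}"
        lines.append(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantRecord]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: multi-allelic records must be split upstream"
                )
            if rec.alts[0].startswith("<"):
                raise ValueError(f"{rec.chrom}:{rec.pos}: symbolic alleles unsupported")
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    variant_id=rec.id or ".",
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, seed=None, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(seed)}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_effects_tsv(calls, path, seed=None) -> None:
    df = pd.DataFrame(
        {
            "variant_id": [c.variant_id for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "effect_class": [c.effect_class.value for c in calls],
            "lof_flag": [int(c.lof_flag) for c in calls],
            "truncation_fraction": [round(c.truncation_fraction, 6) for c in calls],
            "protein_change": [c.protein_change for c in calls],
            "note": [c.note for c in calls],
        }
    )
    write_tsv(df, path, seed=seed)


# ---------------------------------------------------------------------------
# Newick trees and trait maps
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_traits(traits: dict, path, seed=None) -> None:
    df = pd.DataFrame({"taxon": list(traits), "state": [traits[t] for t in traits]})
    write_tsv(df, path, seed=seed)


def read_traits(path) -> dict:
    df = read_tsv(path)
    return dict(zip(df["taxon"].astype(str), df["state"].astype(int)))
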