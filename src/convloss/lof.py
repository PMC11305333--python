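"""Variant-effect classification against single-transcript gene models.

The classifier implements a first-match-wins cascade over the mutation
classes observed in natural prickle-loss alleles (canonical splice-site
disruption, large exonic deletion, frameshift, premature stop, ...), with an
independent translate-the-mutant oracle (:func:`splice_and_translate`) that
decides functionality by actually splicing and translating the edited
sequence.

Rules, stated so they are test-visible:

* only canonical GT/AG splice sites are considered; annotated introns with
  non-canonical termini are flagged ``noncanonical_site`` and never auto-LOF;
* ``stop_gained`` is LOF only when at least 10% of the protein is truncated;
* a deletion removing at least ``large_del_threshold`` coding bases (default
  50) or a complete coding exon is ``large_exonic_deletion`` and LOF even
  when in frame — frame logic alone would miss alleles like a 474-bp
  in-frame exonic deletion;
* indels are left-aligned before classification.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .models import (
    AnnotationSet,
    EffectCall,
    EffectClass,
    GeneModel,
    Genome,
    VariantRecord,
    revcomp,
)

GENE_FLANK = 2000  #: bp beyond the gene span still attributed to the gene


# ---------------------------------------------------------------------------
# Variant normalisation
# ---------------------------------------------------------------------------

def normalize_variant(var: VariantRecord, genome: Genome) -> VariantRecord:
    """Trim shared context and left-align indels.

    Returns a minimal representation: SNVs/MNVs are trimmed to the changed
    bases; pure indels keep one anchor base and are shifted left as far as
    the genomic sequence allows (VCF ambiguity control).
    """
    if "," in var.alt:
        raise ValueError(f"{var.variant_id}: multi-allelic records must be split upstream")
    ref, alt, pos = var.ref, var.alt, var.pos
    seq = genome.seqs[var.chrom]
    if seq[pos - 1: pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"{var.variant_id}: ref allele mismatch with genome at {var.chrom}:{pos}"
        )
    # vt-style normalisation: shave equal trailing bases (extending left when
    # an allele empties), then shave equal leading bases
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        if (not ref or not alt) and pos > 1:
            prev = seq[pos - 2]
            ref, alt = prev + ref, prev + alt
            pos -= 1
            continue
        if not (ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1)):
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantRecord(var.chrom, pos, ref, alt, var.variant_id)


def _variant_geometry(var: VariantRecord):
    """Classify the edit shape after normalisation.

    Returns ``(kind, span, ins_point)`` where ``kind`` is ``snv``, ``ins``,
    ``del`` or ``sub``; ``span`` is the genomic 0-based half-open interval of
    replaced reference bases (excluding the indel anchor) and ``ins_point``
    the between-base insertion coordinate for pure insertions.
    """
    p0 = var.pos0
    if len(var.ref) == 1 and len(var.alt) == 1:
        return "snv", (p0, p0 + 1), None
    if len(var.ref) > len(var.alt) == 1 and var.ref[0] == var.alt[0]:
        return "del", (p0 + 1, p0 + len(var.ref)), None
    if len(var.alt) > len(var.ref) == 1 and var.ref[0] == var.alt[0]:
        return "ins", (p0 + 1, p0 + 1), p0 + 1
    return "sub", (p0, p0 + len(var.ref)), None


def _overlap(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------

def classify_variant(
    gene: GeneModel | None,
    var: VariantRecord,
    genome: Genome,
    large_del_threshold: int = 50,
) -> EffectCall:
    """Classify one variant against one gene model (first match wins).

    ``gene`` may be None (or not overlap the variant within
    :data:`GENE_FLANK`), in which case the call is ``intergenic``.
    """
    if var.alt.startswith("<") or var.ref.startswith("<"):
        raise ValueError(f"{var.variant_id}: symbolic alleles unsupported")
    var = normalize_variant(var, genome)
    if gene is None or not gene.overlaps(var.chrom, var.pos0, GENE_FLANK):
        return EffectCall(EffectClass.INTERGENIC, False, variant_id=var.variant_id)

    kind, span, ins_point = _variant_geometry(var)
    gid = gene.gene_id
    seq = genome.seqs[gene.chrom]
    n_aa = gene.n_codons - 1  # protein length excluding the stop

    def hits_window(win) -> bool:
        if kind == "ins":
            return win[0] < ins_point < win[1]
        return _overlap(span, win) > 0

    # 1. canonical splice sites
    for ti, donor, acceptor in gene.splice_windows():
        for win, cls in ((donor, EffectClass.SPLICE_DONOR), (acceptor, EffectClass.SPLICE_ACCEPTOR)):
            if not hits_window(win):
                continue
            dint = seq[win[0]: win[1]]
            if gene.strand == "-":
                dint = revcomp(dint)
            canonical = dint == ("GT" if cls is EffectClass.SPLICE_DONOR else "AG")
            note = f"intron {ti + 1}" if canonical else f"intron {ti + 1};noncanonical_site"
            return EffectCall(
                cls, canonical, gene_id=gid, variant_id=var.variant_id, note=note
            )

    coding_removed = sum(_overlap(span, c) for c in gene.cds) if kind in ("del", "sub") else 0

    # 2. large exonic deletion (by coding bases removed or a whole coding exon)
    if kind == "del":
        removes_exon = any(span[0] <= cs and ce <= span[1] for cs, ce in gene.cds)
        if coding_removed >= large_del_threshold or (removes_exon and coding_removed > 0):
            frac = coding_removed / gene.cds_len
            return EffectCall(
                EffectClass.LARGE_EXONIC_DELETION,
                True,
                truncation_fraction=frac,
                gene_id=gid,
                variant_id=var.variant_id,
                note=f"{coding_removed} coding bp removed",
            )

    # 3/4. coding indels: frame-shifting vs in-frame
    in_cds_ins = kind == "ins" and any(s < ins_point < e for s, e in gene.cds)
    if (kind == "del" and coding_removed > 0) or in_cds_ins:
        change = len(var.alt) - 1 if kind == "ins" else -coding_removed
        if change % 3 != 0:
            tx = gene.tx_cds_index(span[0] if kind == "del" else ins_point)
            if tx is None:  # deletion starting outside CDS: use first coding base hit
                tx = min(
                    t
                    for t in (gene.tx_cds_index(g) for g in range(span[0], span[1]))
                    if t is not None
                )
            frac = max(0.0, 1.0 - (tx // 3) / n_aa) if n_aa else 0.0
            return EffectCall(
                EffectClass.FRAMESHIFT,
                True,
                truncation_fraction=frac,
                gene_id=gid,
                variant_id=var.variant_id,
                note=f"net {change:+d} coding bp",
            )
        return EffectCall(
            EffectClass.INFRAME_INDEL,
            False,
            gene_id=gid,
            variant_id=var.variant_id,
            note=f"net {change:+d} coding bp",
        )

    # 5. coding SNVs: codon comparison
    if kind in ("snv", "sub"):
        tx = gene.tx_cds_index(var.pos0)
        if tx is not None and kind == "snv":
            c, off = tx // 3, tx % 3
            codon, gpos = gene.codon(genome, c)
            base = var.alt if gene.strand == "+" else revcomp(var.alt)
            # transcription-order offset of this genomic position in the codon
            off = gpos.index(var.pos0)
            new_codon = codon[:off] + base + codon[off + 1:]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(new_codon).translate())
            change = f"p.{aa_ref}{c + 1}{aa_alt}"
            if c == 0 and new_codon != "ATG":
                return EffectCall(
                    EffectClass.START_LOST, True, change, 1.0, gid, var.variant_id
                )
            if aa_ref == "*":
                cls = EffectClass.SYNONYMOUS if aa_alt == "*" else EffectClass.STOP_LOST
                return EffectCall(cls, False, change, 0.0, gid, var.variant_id)
            if aa_alt == "*":
                frac = (n_aa - c) / n_aa if n_aa else 0.0
                return EffectCall(
                    EffectClass.STOP_GAINED, frac >= 0.1, change, frac, gid, var.variant_id
                )
            if aa_alt == aa_ref:
                return EffectCall(EffectClass.SYNONYMOUS, False, change, 0.0, gid, var.variant_id)
            return EffectCall(EffectClass.MISSENSE, False, change, 0.0, gid, var.variant_id)

    # 6. exonic non-CDS / intronic / flanking
    probe = span[0] if kind != "ins" else ins_point
    in_exon = any(s <= probe < e for s, e in gene.exons)
    if in_exon:
        return EffectCall(EffectClass.UTR, False, gene_id=gid, variant_id=var.variant_id)
    gs, ge = gene.span
    if gs <= probe < ge:
        return EffectCall(EffectClass.INTRONIC, False, gene_id=gid, variant_id=var.variant_id)
    return EffectCall(EffectClass.INTERGENIC, False, gene_id=gid, variant_id=var.variant_id)


def classify_all(
    annotation: AnnotationSet,
    variants,
    genome: Genome,
    large_del_threshold: int = 50,
) -> list[EffectCall]:
    """Classify every variant against the gene overlapping it (if any)."""
    return [
        classify_variant(
            annotation.locate(v.chrom, v.pos0, GENE_FLANK), v, genome, large_del_threshold
        )
        for v in variants
    ]


# ---------------------------------------------------------------------------
# Translate-the-mutant oracle
# ---------------------------------------------------------------------------

def _shift_coord(c: int, pos0: int, ref_len: int, delta: int) -> int:
    if c <= pos0:
        return c
    if c >= pos0 + ref_len:
        return c + delta
    return pos0 + min(c - pos0, ref_len + delta)


def _transcript_and_protein(seq: str, exons, cds, strand: str):
    parts = [seq[s:e] for s, e in exons]
    transcript = "".join(parts)
    if strand == "-":
        transcript = revcomp(transcript)

    # transcript coordinate of the translation start (first CDS base in
    # transcription order)
    def tx_of(gpos):
        off = 0
        for s, e in exons:
            if s <= gpos < e:
                off += gpos - s
                break
            off += e - s
        return off if strand == "+" else len(transcript) - 1 - off

    start_g = cds[0][0] if strand == "+" else cds[-1][1] - 1
    tx_start = tx_of(start_g)
    coding = transcript[tx_start:]
    coding = coding[: len(coding) // 3 * 3]
    protein = str(Seq(coding).translate(to_stop=True))
    return transcript, protein


def splice_and_translate(
    gene: GeneModel, genome: Genome, variants
) -> tuple[str, str]:
    """Apply variants, splice the annotated introns out, and translate.

    Returns ``(transcript, protein)`` where the protein runs from the
    annotated start codon to the first stop.  This is the functional oracle:
    whatever the cascade says, the edited gene either still makes the
    wild-type-length protein or it does not.
    """
    seq = genome.seqs[gene.chrom]
    exons = list(gene.exons)
    cds = list(gene.cds)
    for var in sorted(variants, key=lambda v: -v.pos):
        p0 = var.pos0
        if seq[p0: p0 + len(var.ref)] != var.ref:
            raise ValueError(
                f"{var.variant_id}: ref allele mismatch with genome at {var.chrom}:{var.pos}"
            )
        seq = seq[:p0] + var.alt + seq[p0 + len(var.ref):]
        delta = var.net_length
        if delta:
            exons = [
                (_shift_coord(s, p0, len(var.ref), delta), _shift_coord(e, p0, len(var.ref), delta))
                for s, e in exons
            ]
            cds = [
                (_shift_coord(s, p0, len(var.ref), delta), _shift_coord(e, p0, len(var.ref), delta))
                for s, e in cds
            ]
    cds = [(s, e) for s, e in cds if e > s]
    exons = [(s, e) for s, e in exons if e > s]
    return _transcript_and_protein(seq, exons, cds, gene.strand)


def simulate_missplice(
    gene: GeneModel, genome: Genome, disrupted_intron_index: int
) -> tuple[str, EffectCall]:
    """Transcript with the named intron retained, plus its classified consequence.

    ``disrupted_intron_index`` is 0-based in transcription order.  The
    consequence is decided by translating the retained-intron transcript:
    frame disruption when the intron length is not a multiple of 3, a
    premature stop when the retained sequence contains one in frame, and an
    in-frame insertion otherwise.
    """
    if gene.n_introns == 0:
        raise ValueError(f"{gene.gene_id}: gene has no introns")
    if not 0 <= disrupted_intron_index < gene.n_introns:
        raise ValueError(
            f"{gene.gene_id}: intron index {disrupted_intron_index} out of range"
        )
    gi = gene.intron_genomic_index(disrupted_intron_index)
    intron = gene.introns[gi]
    intron_len = intron[1] - intron[0]

    # merge the two exons flanking the retained intron
    exons = list(gene.exons)
    merged = (exons[gi][0], exons[gi + 1][1])
    exons = exons[:gi] + [merged] + exons[gi + 2:]

    seq = genome.seqs[gene.chrom]
    transcript, protein = _transcript_and_protein(seq, exons, gene.cds, gene.strand)
    _, wt_protein = _transcript_and_protein(seq, gene.exons, gene.cds, gene.strand)

    trunc = max(0.0, 1.0 - len(protein) / len(wt_protein)) if wt_protein else 0.0
    if intron_len % 3 != 0:
        call = EffectCall(
            EffectClass.FRAMESHIFT, True, truncation_fraction=trunc, gene_id=gene.gene_id,
            note=f"retained intron {disrupted_intron_index + 1} ({intron_len} bp)",
        )
    elif len(protein) < len(wt_protein):
        call = EffectCall(
            EffectClass.STOP_GAINED, trunc >= 0.1, truncation_fraction=trunc,
            gene_id=gene.gene_id,
            note=f"retained intron {disrupted_intron_index + 1} with in-frame stop",
        )
    else:
        call = EffectCall(
            EffectClass.INFRAME_INDEL, False, gene_id=gene.gene_id,
            note=f"retained intron {disrupted_intron_index + 1} in frame",
        )
    return transcript, call
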