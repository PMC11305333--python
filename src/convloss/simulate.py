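"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: genomes with
embedded gene models, variant sets of requested consequence classes, F2
populations under single- or duplicate-recessive genetics, bulked-segregant
read counts around a planted QTL, paired-species expression compendia with
tunable co-expression conservation, and trees with a planted number of
independent trait losses.  All generators are pure functions of their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .models import (
    AnnotationSet,
    CapacityError,
    EffectClass,
    GeneModel,
    Genome,
    GenomeSequence,
    SimTruth,
    STOP_CODONS,
    VariantRecord,
    revcomp,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]
#: Contains a stop codon in every reading frame (TAA at offsets 1, 5, 9).
#: Embedded mid-intron so that intron retention always truncates translation,
#: mimicking the near-universal presence of in-frame stops in real introns.
_INTRON_STOP_MOTIF = "TTAATTAATTAA"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=n, dtype=np.uint8)].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def gen_genome(n_chrom: int, chrom_len: int, seed: int) -> Genome:
    """Generate ``n_chrom`` chromosomes of uniform-composition random sequence.

    ``chrom_len`` must be at least 10 kb so gene models and flanks fit.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be positive")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    rng = _rng(seed)
    return Genome(
        [GenomeSequence(f"chr{i + 1}", _random_dna(rng, chrom_len)) for i in range(n_chrom)]
    )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _build_gene_local(rng, n_exons, exon_len_range, intron_len_range, utr_len_range):
    """Construct a gene in transcription orientation.

    Returns ``(local_seq, exons_local, cds_local)`` with 0-based half-open
    intervals in local coordinates.  The CDS starts ATG, ends with a stop,
    has no internal in-frame stop; introns are GT..AG with a stop-in-all-
    frames motif embedded in their interior.
    """
    seg = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
    seg[-1] -= int(seg.sum() % 3)
    n_codons = int(seg.sum()) // 3
    codons = ["ATG"]
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    codons.extend(_NONSTOP_CODONS[i] for i in idx)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    cds_seq = "".join(codons)

    bounds = np.concatenate([[0], np.cumsum(seg)])
    cds_parts = [cds_seq[bounds[i]: bounds[i + 1]] for i in range(n_exons)]

    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, size=n_exons - 1)
    introns = []
    for L in intron_lens:
        core = _random_dna(rng, int(L) - 4)
        if len(core) >= len(_INTRON_STOP_MOTIF):
            m = (len(core) - len(_INTRON_STOP_MOTIF)) // 2
            core = core[:m] + _INTRON_STOP_MOTIF + core[m + len(_INTRON_STOP_MOTIF):]
        introns.append("GT" + core + "AG")

    utr5 = _random_dna(rng, int(rng.integers(*utr_len_range)))
    utr3 = _random_dna(rng, int(rng.integers(*utr_len_range)))

    pieces, exons_local, cds_local = [], [], []
    pos = 0
    for i, part in enumerate(cds_parts):
        ex_start = pos
        if i == 0:
            pieces.append(utr5)
            pos += len(utr5)
        cds_local.append((pos, pos + len(part)))
        pieces.append(part)
        pos += len(part)
        if i == n_exons - 1:
            pieces.append(utr3)
            pos += len(utr3)
        exons_local.append((ex_start, pos))
        if i < n_exons - 1:
            pieces.append(introns[i])
            pos += len(introns[i])
    return "".join(pieces), exons_local, cds_local


def gen_gene_models(
    genome: Genome,
    n_genes: int,
    exon_count_range=(2, 7),
    exon_len_range=(90, 300),
    intron_len_range=(60, 400),
    utr_len_range=(20, 60),
    min_gap: int = 5000,
    seed: int = 0,
) -> AnnotationSet:
    """Write ``n_genes`` non-overlapping gene models into ``genome``.

    Genes are packed left to right across chromosomes with gaps of at least
    ``min_gap`` bp; both strands are represented.  Raises
    :class:`~convloss.models.CapacityError` when the request does not fit.
    """
    if intron_len_range[0] < 20:
        raise ValueError("intron length must be >= 20")
    rng = _rng(seed)
    genes = []
    chrom_iter = iter(genome.chroms)
    chrom = next(chrom_iter)
    cursor = min_gap
    for gi in range(n_genes):
        n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        local_seq, exons_local, cds_local = _build_gene_local(
            rng, n_ex, exon_len_range, intron_len_range, utr_len_range
        )
        L = len(local_seq)
        # both strands represented deterministically
        strand = "+" if gi == 0 else "-" if gi == 1 else ("+", "-")[rng.integers(0, 2)]
        while cursor + L + min_gap > len(genome.seqs[chrom]):
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise CapacityError(
                    f"cannot place gene {gi + 1}/{n_genes}: genome capacity exhausted"
                ) from None
            cursor = min_gap
        start = cursor
        if strand == "+":
            gseq = local_seq
            exons = [(start + s, start + e) for s, e in exons_local]
            cds = [(start + s, start + e) for s, e in cds_local]
        else:
            gseq = revcomp(local_seq)
            exons = sorted((start + L - e, start + L - s) for s, e in exons_local)
            cds = sorted((start + L - e, start + L - s) for s, e in cds_local)
        genome.replace_segment(chrom, start, start + L, gseq)
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:04d}", chrom=chrom, strand=strand, exons=exons, cds=cds
            )
        )
        cursor = start + L + min_gap + int(rng.integers(0, min_gap))
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# Variant injection
# ---------------------------------------------------------------------------

_INJECTABLE = {
    "splice_donor": EffectClass.SPLICE_DONOR,
    "splice_acceptor": EffectClass.SPLICE_ACCEPTOR,
    "frameshift_indel": EffectClass.FRAMESHIFT,
    "stop_gained": EffectClass.STOP_GAINED,
    "large_exonic_deletion": EffectClass.LARGE_EXONIC_DELETION,
    "inframe_indel": EffectClass.INFRAME_INDEL,
    "missense": EffectClass.MISSENSE,
    "synonymous": EffectClass.SYNONYMOUS,
    "intronic": EffectClass.INTRONIC,
    "intergenic": EffectClass.INTERGENIC,
}

_LOF_INTENT = {
    EffectClass.SPLICE_DONOR: True,
    EffectClass.SPLICE_ACCEPTOR: True,
    EffectClass.FRAMESHIFT: True,
    EffectClass.STOP_GAINED: True,
    EffectClass.LARGE_EXONIC_DELETION: True,
    EffectClass.INFRAME_INDEL: False,
    EffectClass.MISSENSE: False,
    EffectClass.SYNONYMOUS: False,
    EffectClass.INTRONIC: False,
    EffectClass.INTERGENIC: False,
}

# Intent constraints keeping "intended LOF" semantically true under the
# translate-the-mutant oracle: splice variants need enough downstream coding
# sequence for intron retention to truncate >10% of the protein; frameshifts
# sit in the 5' 60% of the CDS; premature stops truncate >=15%; large
# deletions remove >=12% of coding bases.
_MIN_DOWNSTREAM_FRAC = 0.15
_MAX_FRAMESHIFT_FRAC = 0.60
_MIN_STOP_TRUNCATION = 0.15
_MIN_LARGE_DEL_FRAC = 0.12


class _Occupancy:
    """Tracks per-chromosome intervals already touched by a variant."""

    def __init__(self):
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom, start, end, margin=2) -> bool:
        for s, e in self._iv.get(chrom, []):
            if start - margin < e and s < end + margin:
                return False
        return True

    def add(self, chrom, start, end) -> None:
        self._iv.setdefault(chrom, []).append((start, end))


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _snv_at(genome, gene, gpos, tx_base_alt=None, rng=None):
    """Build an SNV at genomic position ``gpos``.

    ``tx_base_alt`` is the desired alternate base in transcription sense; if
    None a random base different from the reference is chosen (genomic sense).
    """
    ref = genome.seqs[gene.chrom][gpos] if gene is not None else None
    if tx_base_alt is not None:
        alt = tx_base_alt if gene.strand == "+" else revcomp(tx_base_alt)
    else:
        choices = [b for b in _BASES if b != ref]
        alt = choices[rng.integers(0, 3)]
    return ref, alt


def inject_variants(
    genome: Genome,
    annotation: AnnotationSet,
    spec: list[tuple[str, int]],
    seed: int = 0,
    large_del_threshold: int = 50,
    large_del_length: int | None = None,
    max_tries: int = 400,
) -> tuple[list[VariantRecord], SimTruth]:
    """Emit variants of the requested effect classes with a truth table.

    ``spec`` is a list of ``(effect_class, count)`` pairs using the class
    names accepted by the classifier (``frameshift_indel`` maps to
    ``frameshift``).  Requests that cannot be placed (e.g. a splice variant
    when no gene has a suitable intron) are skipped with a logged warning and
    a note in ``SimTruth.skipped``.  ``large_del_length`` forces an exact
    deletion size (e.g. 474) instead of the default sizing rule.
    """
    rng = _rng(seed)
    occ = _Occupancy()
    variants: list[VariantRecord] = []
    truth = SimTruth()
    vid_counter = 0
    genes = list(annotation.genes)

    def emit(chrom, pos0, ref, alt, effect, span):
        nonlocal vid_counter
        vid_counter += 1
        vid = f"v{vid_counter:05d}"
        variants.append(VariantRecord(chrom, pos0 + 1, ref, alt, vid))
        truth.variant_truth.append((vid, effect, _LOF_INTENT[effect]))
        occ.add(chrom, span[0], span[1])

    def try_splice(effect):
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            if gene.n_introns == 0:
                continue
            per_exon = gene.cds_per_exon_tx()
            cds_len = gene.cds_len
            candidates = []
            for ti, donor, acceptor in gene.splice_windows():
                downstream = sum(per_exon[ti + 1:])
                if downstream / cds_len >= _MIN_DOWNSTREAM_FRAC:
                    candidates.append(donor if effect == EffectClass.SPLICE_DONOR else acceptor)
            if not candidates:
                continue
            win = candidates[rng.integers(0, len(candidates))]
            gpos = int(win[0] + rng.integers(0, 2))
            if not occ.free(gene.chrom, gpos, gpos + 1):
                continue
            ref, alt = _snv_at(genome, gene, gpos, rng=rng)
            emit(gene.chrom, gpos, ref, alt, effect, (gpos, gpos + 1))
            return True
        return False

    def try_frameshift():
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            max_tx = int(_MAX_FRAMESHIFT_FRAC * gene.cds_len)
            if max_tx < 12:
                continue
            tx = int(rng.integers(6, max_tx))
            gpos = gene.genomic_cds_pos(tx)
            if rng.integers(0, 2):  # insertion of 1-2 bp after anchor
                ins_len = int(rng.integers(1, 3))
                ref = genome.seqs[gene.chrom][gpos]
                alt = ref + _random_dna(rng, ins_len)
                if not occ.free(gene.chrom, gpos, gpos + 2):
                    continue
                emit(gene.chrom, gpos, ref, alt, EffectClass.FRAMESHIFT, (gpos, gpos + 2))
            else:  # deletion of 1, 2 or 4 bp within one CDS segment
                dlen = (1, 2, 4)[rng.integers(0, 3)]
                seg = next(((s, e) for s, e in gene.cds if s <= gpos < e), None)
                if seg is None or gpos + dlen + 3 > seg[1] or gpos - 1 < seg[0]:
                    continue
                a = gpos - 1
                if not occ.free(gene.chrom, a, gpos + dlen):
                    continue
                ref = genome.seqs[gene.chrom][a: gpos + dlen]
                emit(gene.chrom, a, ref, ref[0], EffectClass.FRAMESHIFT, (a, gpos + dlen))
            return True
        return False

    def try_stop_gained():
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            L = gene.n_codons - 1  # protein length excluding stop
            c_max = int((1 - _MIN_STOP_TRUNCATION) * L)
            if c_max < 3:
                continue
            c = int(rng.integers(2, c_max))
            codon, gpos = gene.codon(genome, c)
            if codon in STOP_CODONS:
                continue
            hits = []
            for off in range(3):
                for b in _BASES:
                    if b == codon[off]:
                        continue
                    new = codon[:off] + b + codon[off + 1:]
                    if new in STOP_CODONS:
                        hits.append((off, b))
            if not hits:
                continue
            off, b = hits[rng.integers(0, len(hits))]
            g = gpos[off]
            if not occ.free(gene.chrom, g, g + 1):
                continue
            ref, alt = _snv_at(genome, gene, g, tx_base_alt=b)
            emit(gene.chrom, g, ref, alt, EffectClass.STOP_GAINED, (g, g + 1))
            return True
        return False

    def try_large_del():
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            need = large_del_length or max(
                large_del_threshold, math.ceil(_MIN_LARGE_DEL_FRAC * gene.cds_len)
            )
            segs = [(s, e) for s, e in gene.cds if e - s >= need + 6]
            if not segs:
                continue
            s, e = segs[rng.integers(0, len(segs))]
            start = int(rng.integers(s + 3, e - need - 3 + 1))
            # keep the removed block in the 5' 60% of the CDS so the intended
            # LOF label holds under the translation oracle even for in-frame
            # or 3'-frameshifting deletions
            tx_lo = min(gene.tx_cds_index(start), gene.tx_cds_index(start + need - 1))
            if tx_lo is None or tx_lo > _MAX_FRAMESHIFT_FRAC * gene.cds_len:
                continue
            a = start - 1
            if not occ.free(gene.chrom, a, start + need):
                continue
            ref = genome.seqs[gene.chrom][a: start + need]
            emit(gene.chrom, a, ref, ref[0], EffectClass.LARGE_EXONIC_DELETION, (a, start + need))
            return True
        return False

    def try_inframe():
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            ncod = gene.n_codons
            dcod = (1, 2)[rng.integers(0, 2)]
            if ncod < dcod + 4:
                continue
            c = int(rng.integers(1, ncod - 1 - dcod))
            # genomic span of the removed codons must be contiguous
            tx_lo, tx_hi = 3 * c, 3 * (c + dcod) - 1
            g_all = sorted(gene.genomic_cds_pos(t) for t in range(tx_lo, tx_hi + 1))
            if g_all[-1] - g_all[0] != len(g_all) - 1:
                continue
            a = g_all[0] - 1
            seg = next(((s, e) for s, e in gene.cds if s <= g_all[0] < e), None)
            if seg is None or a < seg[0] or g_all[-1] + 1 > seg[1]:
                continue
            if not occ.free(gene.chrom, a, g_all[-1] + 1):
                continue
            ref = genome.seqs[gene.chrom][a: g_all[-1] + 1]
            emit(gene.chrom, a, ref, ref[0], EffectClass.INFRAME_INDEL, (a, g_all[-1] + 1))
            return True
        return False

    def try_codon_snv(effect):
        want_syn = effect == EffectClass.SYNONYMOUS
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            c = int(rng.integers(1, gene.n_codons - 1))
            codon, gpos = gene.codon(genome, c)
            if codon in STOP_CODONS:
                continue
            aa = _translate_codon(codon)
            offs = [2] if want_syn else [0, 1, 2]
            hits = []
            for off in offs:
                for b in _BASES:
                    if b == codon[off]:
                        continue
                    new = codon[:off] + b + codon[off + 1:]
                    if new in STOP_CODONS:
                        continue
                    same = _translate_codon(new) == aa
                    if same == want_syn:
                        hits.append((off, b))
            if not hits:
                continue
            off, b = hits[rng.integers(0, len(hits))]
            g = gpos[off]
            if not occ.free(gene.chrom, g, g + 1):
                continue
            ref, alt = _snv_at(genome, gene, g, tx_base_alt=b)
            emit(gene.chrom, g, ref, alt, effect, (g, g + 1))
            return True
        return False

    def try_intronic():
        for _ in range(max_tries):
            gene = genes[rng.integers(0, len(genes))]
            introns = [iv for iv in gene.introns if iv[1] - iv[0] >= 12]
            if not introns:
                continue
            s, e = introns[rng.integers(0, len(introns))]
            g = int(rng.integers(s + 3, e - 3))
            if not occ.free(gene.chrom, g, g + 1):
                continue
            ref, alt = _snv_at(genome, gene, g, rng=rng)
            emit(gene.chrom, g, ref, alt, EffectClass.INTRONIC, (g, g + 1))
            return True
        return False

    def try_intergenic():
        spans = {}
        for g in genes:
            spans.setdefault(g.chrom, []).append(g.span)
        chroms = genome.chroms
        for _ in range(max_tries):
            chrom = chroms[rng.integers(0, len(chroms))]
            g = int(rng.integers(100, len(genome.seqs[chrom]) - 100))
            if any(s - 2100 <= g < e + 2100 for s, e in spans.get(chrom, [])):
                continue
            if not occ.free(chrom, g, g + 1):
                continue
            ref = genome.seqs[chrom][g]
            alt = [b for b in _BASES if b != ref][rng.integers(0, 3)]
            emit(chrom, g, ref, alt, EffectClass.INTERGENIC, (g, g + 1))
            return True
        return False

    dispatch = {
        EffectClass.SPLICE_DONOR: lambda: try_splice(EffectClass.SPLICE_DONOR),
        EffectClass.SPLICE_ACCEPTOR: lambda: try_splice(EffectClass.SPLICE_ACCEPTOR),
        EffectClass.FRAMESHIFT: try_frameshift,
        EffectClass.STOP_GAINED: try_stop_gained,
        EffectClass.LARGE_EXONIC_DELETION: try_large_del,
        EffectClass.INFRAME_INDEL: try_inframe,
        EffectClass.MISSENSE: lambda: try_codon_snv(EffectClass.MISSENSE),
        EffectClass.SYNONYMOUS: lambda: try_codon_snv(EffectClass.SYNONYMOUS),
        EffectClass.INTRONIC: try_intronic,
        EffectClass.INTERGENIC: try_intergenic,
    }

    for name, count in spec:
        if name not in _INJECTABLE:
            raise ValueError(f"unknown effect class {name!r}")
        effect = _INJECTABLE[name]
        for _ in range(count):
            if not dispatch[effect]():
                reason = "no placement found"
                log.warning("inject_variants: skipped one %s request (%s)", name, reason)
                truth.skipped.append((effect, reason))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, truth


# ---------------------------------------------------------------------------
# F2 populations
# ---------------------------------------------------------------------------

_GENO_LABELS = np.array(["hom_ref", "het", "hom_alt"])


def gen_f2_population(
    model: str,
    n: int,
    distortion: float = 0.0,
    penetrance: float = 1.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate an F2 population table.

    ``model`` is ``single_recessive`` (one causal locus, ``pl``) or
    ``duplicate_recessive`` (two unlinked loci ``pl``/``pl2``; homozygous
    mutant at either suppresses the trait — duplicate-recessive 9:7
    epistasis).  Genotypes are drawn 1:2:1 per locus; ``distortion`` is a
    viability selection coefficient against the homozygous mutant class;
    mutant genotypes express the mutant phenotype with probability
    ``penetrance``.  Phenotype labels: ``trait_absent`` = prickleless.
    """
    if model not in ("single_recessive", "duplicate_recessive"):
        raise ValueError(f"unknown model {model!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < penetrance <= 1:
        raise ValueError("penetrance must be in (0, 1]")
    rng = _rng(seed)
    loci = ["pl"] if model == "single_recessive" else ["pl", "pl2"]
    w = np.array([1.0, 2.0, 1.0 - distortion])
    p = w / w.sum()
    data = {"individual_id": [f"ind{i + 1:05d}" for i in range(n)]}
    geno = {}
    for locus in loci:
        geno[locus] = rng.choice(3, size=n, p=p)
        data[f"geno_{locus}"] = _GENO_LABELS[geno[locus]]
    mutant = np.zeros(n, dtype=bool)
    for locus in loci:
        mutant |= geno[locus] == 2
    expressed = mutant & (rng.random(n) < penetrance)
    data["phenotype"] = np.where(expressed, "trait_absent", "trait_present")
    df = pd.DataFrame(data)
    if missing_rate > 0:
        for locus in loci:
            mask = rng.random(n) < missing_rate
            df.loc[mask, f"geno_{locus}"] = "missing"
    return df


# ---------------------------------------------------------------------------
# Bulked-segregant counts
# ---------------------------------------------------------------------------

def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def gen_bsa_counts(
    chrom_len: int,
    qtl_position: int,
    n_high_bulk: int = 20,
    n_low_bulk: int = 20,
    depth: int = 50,
    n_snps: int = 200,
    map_rate: float = 4.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-SNP bulk allele depths around a recessive causal locus.

    High bulk = phenotype-mutant F2s (homozygous ``aa`` at the QTL); low bulk
    = wild-phenotype F2s (1/3 AA : 2/3 Aa).  A marker at recombination
    fraction ``r`` from the QTL (Haldane transform of ``map_rate`` cM/Mb map
    distance) carries the mutant-parent allele with probability 1-r per
    high-bulk allele; low-bulk gametes carry it with probability r (A
    gametes) or 1-r (a gametes).  Read counts are binomial at the realized
    bulk allele frequency with the stated ``depth``.
    """
    if not 0 <= qtl_position < chrom_len:
        raise ValueError("qtl_position outside chromosome")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    pos = np.sort(rng.choice(chrom_len, size=n_snps, replace=False))
    d_cm = np.abs(pos - qtl_position) / 1e6 * map_rate
    r = haldane_r(d_cm)

    # high bulk: all 2*n_high alleles are mutant-parent w.p. 1-r
    alt_high = rng.binomial(2 * n_high_bulk, 1.0 - r)
    p_high = alt_high / (2 * n_high_bulk)
    alt_depth_high = rng.binomial(depth, p_high)

    # low bulk: individuals from the A_ class; AA w.p. 1/3 else Aa
    n_aa = rng.binomial(n_low_bulk, 1.0 / 3.0, size=n_snps)
    n_het = n_low_bulk - n_aa
    alt_low = (
        rng.binomial(2 * n_aa, r)
        + rng.binomial(n_het, r)
        + rng.binomial(n_het, 1.0 - r)
    )
    p_low = alt_low / (2 * n_low_bulk)
    alt_depth_low = rng.binomial(depth, p_low)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref_depth_high": depth - alt_depth_high,
            "alt_depth_high": alt_depth_high,
            "ref_depth_low": depth - alt_depth_low,
            "alt_depth_low": alt_depth_low,
        }
    )
    return df, SimTruth(qtl_position=int(qtl_position))


# ---------------------------------------------------------------------------
# Expression pairs
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Parameters of the latent-factor co-expression simulator.

    ``rho`` is the probability that an ortholog pair keeps its co-expression
    module across species — the synthetic stand-in for cross-species
    co-expression conservation strength.
    """

    n_genes_per_species: int = 200
    n_samples: int = 200
    n_modules: int = 20
    rho: float = 1.0
    noise_sd: float = 0.1
    paralog_rate: float = 0.0
    n_tissues: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.n_modules > self.n_genes_per_species:
            raise ValueError("n_modules must be <= n_genes")
        if self.n_modules == 0 and self.rho > 0:
            raise ValueError("n_modules=0 is incompatible with rho > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class ExpressionPair:
    """Two species' expression matrices (genes x samples, nonnegative)."""

    expr_a: pd.DataFrame
    expr_b: pd.DataFrame
    tissues_a: pd.Series | None = None
    tissues_b: pd.Series | None = None


def _species_matrix(rng, modules, n_samples, n_modules, noise_sd, prefix):
    n = len(modules)
    factors = rng.normal(size=(max(n_modules, 1), n_samples))
    loadings = rng.uniform(0.5, 1.5, size=n)
    z = loadings[:, None] * factors[modules] + noise_sd * rng.normal(size=(n, n_samples))
    samples = [f"{prefix}_s{j + 1:04d}" for j in range(n_samples)]
    genes = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(np.exp(z), index=genes, columns=samples)


def gen_expression_pair(
    config: ExpressionSimConfig,
) -> tuple[ExpressionPair, pd.DataFrame, SimTruth]:
    """Generate paired-species expression matrices and an ortholog map.

    Latent-factor model: each gene belongs to one module; its (log-scale)
    expression is a loading times the module factor plus independent Gaussian
    noise, exponentiated so values are nonnegative.  An ortholog pair shares
    its module with probability ``rho``; otherwise the species-2 member is
    reassigned to a random other module.  Paralogs are extra species-2 genes
    duplicated from existing ones with independent module reassignment.
    """
    config.validate()
    rng = _rng(config.seed)
    n = config.n_genes_per_species
    m = config.n_modules
    modules_a = rng.integers(0, max(m, 1), size=n)
    conserved = rng.random(n) < config.rho
    modules_b = modules_a.copy()
    if m > 1:
        for i in np.nonzero(~conserved)[0]:
            shift = int(rng.integers(1, m))
            modules_b[i] = (modules_a[i] + shift) % m

    expr_a = _species_matrix(rng, modules_a, config.n_samples, m, config.noise_sd, "a")
    genes_a = list(expr_a.index)

    # paralogs: duplicate species-2 genes with fresh module assignments
    n_par = int(round(config.paralog_rate * n))
    par_src = rng.choice(n, size=n_par, replace=False) if n_par else np.array([], dtype=int)
    par_modules = rng.integers(0, max(m, 1), size=n_par)
    modules_b_full = np.concatenate([modules_b, par_modules])
    expr_b = _species_matrix(rng, modules_b_full, config.n_samples, m, config.noise_sd, "b")
    genes_b = list(expr_b.index)

    pairs = [(genes_a[i], genes_b[i]) for i in range(n)]
    pairs += [(genes_a[src], genes_b[n + j]) for j, src in enumerate(par_src)]
    orthology = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    tissues_a = tissues_b = None
    if config.n_tissues > 1:
        tissues_a = pd.Series(
            [f"tissue{j % config.n_tissues + 1}" for j in range(config.n_samples)],
            index=expr_a.columns,
        )
        tissues_b = pd.Series(
            [f"tissue{j % config.n_tissues + 1}" for j in range(config.n_samples)],
            index=expr_b.columns,
        )
    truth = SimTruth(
        conservation_rho=config.rho,
        extras={
            "modules_a": dict(zip(genes_a, modules_a.tolist())),
            "modules_b": dict(zip(genes_b, modules_b_full.tolist())),
            "conserved": dict(zip(genes_a, conserved.tolist())),
        },
    )
    return ExpressionPair(expr_a, expr_b, tissues_a, tissues_b), orthology, truth


# ---------------------------------------------------------------------------
# Trees with planted losses
# ---------------------------------------------------------------------------

def _random_topology(rng, n_taxa: int) -> dendropy.Tree:
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first = dendropy.Node(taxon=tns.get_taxon(taxa[0]))
    second = dendropy.Node(taxon=tns.get_taxon(taxa[1]))
    root.add_child(first)
    root.add_child(second)
    attachable = [first, second]
    for label in taxa[2:]:
        target = attachable[rng.integers(0, len(attachable))]
        parent = target.parent_node
        joint = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        joint.add_child(leaf)
        attachable.extend([joint, leaf])
    return tree


def gen_tree_with_losses(
    n_taxa: int, n_loss_events: int, seed: int = 0, max_tries: int = 5000
) -> tuple[dendropy.Tree, dict[str, int], SimTruth]:
    """Random rooted binary tree with exactly ``n_loss_events`` planted losses.

    The trait starts present (state 1) at the root; chosen edges switch 1->0
    irreversibly, so all taxa below a loss edge have state 0.  The chosen
    edge set is constrained so the losses remain distinguishable (no loss
    edge nested under another, and no unlabelled clade becomes entirely 0),
    i.e. Dollo counting on the output returns ``n_loss_events`` exactly.
    """
    from .comparative import min_independent_origins

    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if n_loss_events < 0 or n_loss_events > n_taxa - 1:
        raise ValueError("infeasible loss event count")
    rng = _rng(seed)
    tree = _random_topology(rng, n_taxa)
    leaves = [nd for nd in tree.leaf_node_iter()]
    if n_loss_events == 0:
        traits = {lf.taxon.label: 1 for lf in leaves}
        return tree, traits, SimTruth(loss_events=0)
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    for _ in range(max_tries):
        chosen = set(rng.choice(len(edges), size=n_loss_events, replace=False).tolist())
        chosen_nodes = {id(edges[i]) for i in chosen}
        traits = {}
        for lf in leaves:
            state = 1
            nd = lf
            while nd is not None:
                if id(nd) in chosen_nodes:
                    state = 0
                    break
                nd = nd.parent_node
            traits[lf.taxon.label] = state
        if min_independent_origins(tree, traits, mode="dollo_loss") == n_loss_events:
            return tree, traits, SimTruth(loss_events=n_loss_events)
    raise CapacityError(
        f"could not plant {n_loss_events} distinguishable losses on {n_taxa} taxa"
    )
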