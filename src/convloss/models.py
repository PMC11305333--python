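"""Shared domain objects: genome sequences, gene models, variants, effect calls.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open intervals on the forward
genomic strand.  GFF3 is written 1-based inclusive and VCF 1-based with the
anchored-base indel convention; conversion happens only at I/O boundaries
(:mod:`convloss.io`).  :class:`VariantRecord.pos` is 1-based, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class CapacityError(RuntimeError):
    """Requested construction does not fit in the available sequence."""


class EffectClass(str, Enum):
    """Consequence classes for a variant against a single-transcript gene model."""

    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    START_LOST = "start_lost"
    STOP_LOST = "stop_lost"
    LARGE_EXONIC_DELETION = "large_exonic_deletion"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"


#: Classes that may carry a loss-of-function flag (stop_gained only when the
#: truncation-fraction rule is met).
LOF_ELIGIBLE = frozenset(
    {
        EffectClass.SPLICE_DONOR,
        EffectClass.SPLICE_ACCEPTOR,
        EffectClass.FRAMESHIFT,
        EffectClass.STOP_GAINED,
        EffectClass.START_LOST,
        EffectClass.LARGE_EXONIC_DELETION,
    }
)


@dataclass
class GenomeSequence:
    """One chromosome/contig of plain A/C/G/T sequence."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.chrom_id}: empty sequence")
        if not _VALID_BASES.issuperset(self.sequence):
            bad = set(self.sequence) - _VALID_BASES
            raise ValueError(f"{self.chrom_id}: non-ACGT characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class Genome:
    """A mutable collection of chromosome sequences keyed by id."""

    def __init__(self, records):
        if isinstance(records, dict):
            records = [GenomeSequence(c, s) for c, s in records.items()]
        self.seqs: dict[str, str] = {}
        for rec in records:
            if rec.chrom_id in self.seqs:
                raise ValueError(f"duplicate chromosome id {rec.chrom_id!r}")
            self.seqs[rec.chrom_id] = rec.sequence

    @property
    def chroms(self) -> list[str]:
        return list(self.seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]

    def replace_segment(self, chrom: str, start: int, end: int, new: str) -> None:
        """Overwrite ``[start, end)`` with ``new`` (must be the same length)."""
        if len(new) != end - start:
            raise ValueError("replacement length mismatch")
        s = self.seqs[chrom]
        self.seqs[chrom] = s[:start] + new + s[end:]

    def records(self):
        return [GenomeSequence(c, s) for c, s in self.seqs.items()]


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene.

    ``exons`` and ``cds`` are lists of 0-based half-open ``(start, end)``
    intervals in ascending genomic order regardless of strand; transcription
    order is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivs:
                if e <= s:
                    raise ValueError(f"{self.gene_id}: empty {name} interval {(s, e)}")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_id}: {name} overlap/unsorted")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment outside exons")
        if self.cds and self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_len} not divisible by 3")

    # -- geometry -----------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in ascending genomic order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    def overlaps(self, chrom: str, pos0: int, flank: int = 0) -> bool:
        s, e = self.span
        return chrom == self.chrom and s - flank <= pos0 < e + flank

    # -- transcription-order helpers ---------------------------------------
    def intron_tx_index(self, genomic_index: int) -> int:
        """Map an ascending-order intron index to transcription order."""
        return genomic_index if self.strand == "+" else self.n_introns - 1 - genomic_index

    def intron_genomic_index(self, tx_index: int) -> int:
        return tx_index if self.strand == "+" else self.n_introns - 1 - tx_index

    def splice_windows(self):
        """Yield ``(tx_intron_index, donor_window, acceptor_window)``.

        Windows are genomic 0-based half-open 2-bp intervals covering the
        canonical GT (donor, transcriptional 5' of the intron) and AG
        (acceptor, 3') dinucleotides.
        """
        for gi, (s, e) in enumerate(self.introns):
            ti = self.intron_tx_index(gi)
            if self.strand == "+":
                yield ti, (s, s + 2), (e - 2, e)
            else:
                yield ti, (e - 2, e), (s, s + 2)

    def cds_flat(self) -> list[tuple[int, int]]:
        """CDS segments with cumulative offsets: ``(start, end)`` ascending."""
        return list(self.cds)

    def tx_cds_index(self, gpos: int):
        """Transcription-order CDS offset of a genomic position, or None."""
        cum = 0
        idx = None
        for s, e in self.cds:
            if s <= gpos < e:
                idx = cum + (gpos - s)
                break
            cum += e - s
        if idx is None:
            return None
        return idx if self.strand == "+" else self.cds_len - 1 - idx

    def genomic_cds_pos(self, tx_index: int) -> int:
        """Genomic position of a transcription-order CDS offset."""
        if self.strand == "-":
            tx_index = self.cds_len - 1 - tx_index
        cum = 0
        for s, e in self.cds:
            if tx_index < cum + (e - s):
                return s + (tx_index - cum)
            cum += e - s
        raise IndexError(tx_index)

    def codon(self, genome: Genome, codon_index: int) -> tuple[str, list[int]]:
        """Return ``(codon, genomic_positions)`` for a transcription-order codon.

        Positions are listed in transcription order; bases are complemented
        for minus-strand genes so the codon reads in coding sense.
        """
        chrom_seq = genome.seqs[self.chrom]
        gpos = [self.genomic_cds_pos(3 * codon_index + i) for i in range(3)]
        bases = [chrom_seq[g] for g in gpos]
        if self.strand == "-":
            bases = [b.translate(_COMPLEMENT) for b in bases]
        return "".join(bases), gpos

    def cds_per_exon_tx(self) -> list[int]:
        """Coding bases per exon, in transcription order."""
        out = []
        for es, ee in self.exons:
            n = sum(max(0, min(ee, ce) - max(es, cs)) for cs, ce in self.cds)
            out.append(n)
        return out if self.strand == "+" else out[::-1]


@dataclass
class AnnotationSet:
    """Gene models for one genome, with simple positional lookup."""

    genes: list[GeneModel] = field(default_factory=list)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def locate(self, chrom: str, pos0: int, flank: int = 2000):
        """Return the gene whose span +/- ``flank`` contains ``pos0``, or None."""
        for g in self.genes:
            if g.overlaps(chrom, pos0, flank):
                return g
        return None


@dataclass(frozen=True)
class VariantRecord:
    """A genomic change in VCF convention: 1-based ``pos``, anchored indels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")
        for allele in (self.ref, self.alt):
            if not allele or not _VALID_BASES.issuperset(allele):
                raise ValueError(f"{self.variant_id}: bad allele {allele!r}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class EffectCall:
    """Classified consequence of a variant with a loss-of-function flag."""

    effect_class: EffectClass
    lof_flag: bool
    protein_change: str = ""
    truncation_fraction: float = 0.0
    gene_id: str = ""
    variant_id: str = ""
    note: str = ""


@dataclass
class SimTruth:
    """Ground truth attached to simulator output.

    ``variant_truth`` rows are ``(variant_id, intended_effect_class,
    intended_lof_flag)``; ``skipped`` records requests the generator could not
    honour, as ``(effect_class, reason)``.
    """

    variant_truth: list[tuple[str, EffectClass, bool]] = field(default_factory=list)
    skipped: list[tuple[EffectClass, str]] = field(default_factory=list)
    qtl_position: int | None = None
    loss_events: int | None = None
    conservation_rho: float | None = None
    extras: dict = field(default_factory=dict)
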