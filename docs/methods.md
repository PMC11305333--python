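# Methods

This note documents the models implemented in `convloss`, the assumptions
behind the synthetic-data generators, the defaults that matter, and the
design choices made where the design was genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates, formats and randomness

Internal coordinates are 0-based half-open throughout; GFF3 is written
1-based inclusive and VCF 1-based with the anchored-base indel convention,
so the standards are matched bit-exactly at I/O boundaries.  Indels are
left-aligned (vt-style: shave equal trailing bases, extend left when an
allele empties, then shave equal leading bases) before classification, which
controls VCF representational ambiguity.

All randomness flows through `numpy.random.default_rng`; every generator is
a pure function of its seed.  The pipeline derives per-stage child seeds
from the single global seed via `numpy.random.SeedSequence.spawn`, so each
stage is individually reproducible and `summary.json` is byte-identical
across reruns.  Output files carry a provenance comment (tool version, seed)
wherever the format permits comments.

## Synthetic gene models

Genes are built in transcription orientation as UTR5 + CDS exons + UTR3 with
GT..AG introns, then reverse-complemented for minus-strand placement.  The
CDS starts ATG, ends with a stop, and contains no internal in-frame stop by
construction (codons drawn from the 61 sense codons).  Genes are packed
without overlap, separated by at least 5 kb so the ±2 kb gene-flank
attribution window never straddles two genes; an infeasible packing raises a
capacity error rather than silently truncating.

Each intron carries, embedded mid-sequence, a short motif containing a stop
codon in all three reading frames.  Real introns essentially always contain
in-frame stops; the motif makes that property deterministic, so
intron-retention mis-splicing reliably truncates translation.  This is a
modelling choice about what passing tests show: splice-site LOF calls are
validated against retention-driven truncation, not against a splice-strength
model.

## Variant injection and "intended LOF" semantics

`inject_variants` emits variants whose requested class the classifier will
reproduce, together with a truth table.  Four intent constraints keep the
intended LOF labels semantically true under the translation oracle (mutant
protein < 90% of wild-type length):

* splice variants are only injected at introns with ≥ 15% of the coding
  sequence downstream, so retention truncates more than the 10% stop-gained
  rule requires;
* frameshifts are placed in the 5′ 60% of the CDS (a shifted frame then hits
  a stop long before the 90% mark with overwhelming probability);
* premature stops are injected with truncation fraction ≥ 0.15;
* large deletions are sized ≥ max(threshold, 12% of coding bases) and also
  placed in the 5′ 60% of the CDS — a 3′-proximal deletion can otherwise
  leave a ≥ 90%-length protein and make the label vacuous.

Requests that cannot be placed (e.g. a splice variant in a single-exon gene)
are skipped with a logged warning and recorded in the truth table, never
silently dropped.

## Effect classification

The cascade is first-match-wins: (1) canonical splice donor/acceptor
dinucleotides (a non-GT/AG annotated site is flagged `noncanonical_site` and
never auto-LOF — splice calls are "probable", and a conservative rule is
testable); (2) deletions removing ≥ `large_del_threshold` coding bp
(default 50) or a complete coding exon are `large_exonic_deletion` and LOF
even in frame, because frame logic alone would clear a 474-bp in-frame
exonic deletion that plainly destroys the protein; (3/4) coding indels by
frame; (5) coding SNVs by codon comparison, with `stop_gained` LOF only when
≥ 10% of the protein is lost (no NMD 50-nt rule: the threshold is simple,
declared, and test-visible); (6) UTR/intronic/intergenic.  Classification is
total — every variant receives exactly one class — and strand-invariant,
which the tests check by mirror construction.

The oracle (`splice_and_translate`) applies variants to the chromosome
sequence while shifting annotation coordinates through each edit, extracts
and concatenates exons on the transcription strand, and translates from the
annotated start to the first stop.  It shares no code path with the cascade.

## F2 genetics

Genotypes are drawn 1:2:1 per locus; `duplicate_recessive` uses two unlinked
loci where homozygous mutant at either suppresses the trait — the minimal
two-locus model consistent with a second unlinked recessive locus producing
the same phenotype, and the source of the 9:7 F2 ratio (mutant fraction
1 − (3/4)² = 7/16).  `distortion` is a viability selection coefficient
against the homozygous mutant class; `penetrance` thins mutant-genotype
individuals into the wild-type phenotype class.  Missing genotypes are
excluded pairwise per test and counted, never imputed.

All χ² tests use the uncorrected Pearson statistic: the printed pair
(χ² = 0.52, df = 1 → p = 0.47) is consistent with the uncorrected statistic,
and type-I error at n = 400 is calibrated to 0.05 ± 0.01 in the suite.
Model selection ranks 3:1, 9:7, 13:3 and 15:1 by p-value with ties broken
toward fewer loci.

One test deviates from a naive "≥ 98/100 seeds pass the 1:2:1 χ² at
α = 0.01" phrasing: for a perfectly calibrated generator that event itself
fails ~8% of the time, so the suite instead asserts an exact binomial bound
on the rejection count (≤ 7/100, false-alarm ~10⁻⁵) plus a pooled-count fit.

## Bulked-segregant model

The high bulk contains phenotype-mutant F2s (homozygous *aa* at the QTL);
the low bulk draws from the *A_* class (1/3 *AA* : 2/3 *Aa*).  At a marker
with recombination fraction r (Haldane transform r = (1 − e^(−2d/100))/2 of
the cM distance, default map rate 4 cM/Mb), each high-bulk allele is the
mutant-parent allele with probability 1 − r; low-bulk gametes carry it with
probability r (A gametes) or 1 − r (a gametes).  Reads are binomial at the
realized bulk frequency.  The resulting expectation is
E[Δ] = (1 − r) − (r/3 + 1/3) = 2/3 − (4/3)r: 2/3 at the QTL, 0 unlinked.
Markers are sampled independently given bulk membership; shared
recombination breakpoints along a chromosome are not modelled, so
marker-to-marker noise is slightly less correlated than in real bulks.

Windows use unweighted SNP means (depth already gates inclusion through
`min_depth`); defaults are window 2 Mb, step 50 kb, `min_depth` 10, α = 0.01,
`min_run` 5 consecutive above-band windows, `merge_gap` 2.  The null band is
simulated (10,000 unselected-bulk replicates by default) rather than
analytic, because the finite-bulk + finite-depth compound distribution has
no convenient closed form.  The study's own bulk sizes and depths are not
public; the benchmark conditions (50 Mb chromosome, 20+20 bulks, depth 50,
2000 SNPs, 50 seeded runs) are this package's declared fixture, and the
reported interval widths are regression-tracked, not compared to any
published interval.

## Co-expression conservation

Networks are Spearman correlations with each gene's row rank-standardized to
(0, 1] (mid-rank ties; self-similarity set to the maximum correlation so a
perfect correlate ties with self at the row maximum).  Spearman rather than
Pearson: meta-analysis expression compendia are heterogeneous, and rank
invariance under monotone transforms is what makes the scores property-
testable.  A single pooled network per species is built; per-study
aggregation across compendia is a noted alternative, not implemented.

Neighbor voting: positives are the species-B orthologs of gene A's top-k
(default k = 10, declared and reported — no published neighbor count exists
to match) co-expression neighbors; candidates are all species-B genes with
at least one A-ortholog, excluding gene B itself, so AUROC compares like
with like.  Many-to-many orthologs expand the positive set.  AUROC uses the
Mann–Whitney rank-sum formula with mid-rank ties, verified in the suite
against exhaustive pair counting.  Undefined scores (empty positive or
negative sets, constant-expression genes) are explicit nulls, never 0.5.

The generator's latent-factor model assigns each gene one module; log-scale
expression is loading × module factor + Gaussian noise, exponentiated to
keep values nonnegative.  An ortholog pair keeps its module with probability
ρ — the tunable stand-in for conservation strength.  Benchmark conditions:
ρ = 1, noise SD 0.1, 500 samples, 200 genes in 20 modules, 25 scored pairs,
100 orthology permutations for the chance control.  What passing shows:
the scoring machinery recovers planted conservation and is calibrated at
chance under permutation — not that any particular real AUROC value (such
as one measured on thousands of real samples) is reproducible here.

τ tissue specificity is computed on log2(x+1)-scaled per-tissue means:
τ = Σ(1 − x_i/max x_i)/(N − 1), 0 for uniform and 1 for single-tissue
expression; all-zero genes get a null with a reason.

## Parsimony and allele counting

Fitch is the standard two-pass set method (verified against exhaustive
ancestral-labeling minimisation); Dollo fixes the root at trait-present,
forbids re-gain, and counts maximal all-absent leaf clades.  Polytomies are
resolved deterministically (left-branching by input order) before Fitch, and
counts on resolved trees are lower bounds.  The tree generator plants losses
on edges constrained so no loss nests under another and no unlabelled clade
becomes entirely absent — planted losses therefore stay distinguishable and
Dollo recovers the planted count exactly, by rejection sampling with a
bounded retry budget.

Allele descriptors canonicalize to (gene, effect class, CDS-relative
position key), case-folded, so the same mutation observed in two species
compares equal.  Collapsing shared descriptors gives a conservative lower
bound on independent origins; both collapsed and per-observation counts are
exposed.  The packaged survey table is a synthetic reconstruction (see its
header): the allele arithmetic — 18 observations, 16 distinct alleles, two
cross-continental shared-allele species pairs — is faithful, while position
keys and unnamed survey taxa are schematic placeholders.

Synteny chaining maps anchors to index pairs and takes longest strictly
increasing/decreasing subsequences per orientation; blocks need ≥ 3 anchors
(standard collinearity practice, configurable), and retention is the best
chain's share of anchors.

## Pipeline

`run_pipeline` executes six stages (simulate, classify, segregate, map,
score conservation, count losses) in dependency order, halting on the first
failure with a structured error.  Artifacts are checksummed into a MANIFEST;
on rerun, analysis stages whose artifacts still match are skipped, while the
simulate stage is always re-executed — it is deterministic and cheap, and
re-running it rebuilds the in-memory state downstream stages consume.  The
resolved configuration is written beside the outputs, and unknown
configuration keys are rejected rather than ignored.

## Problem sizes

The suite and the reproduction script run at deliberately desk-scale sizes,
chosen as the package's own benchmark conditions: 1,000 injected variants
across 60 genes on 1.2 Mb of sequence for the oracle comparison; 50 BSA
simulations on a 50 Mb chromosome; 200-gene, 500-sample expression pairs;
100 8-taxon trees for the brute-force parsimony oracle (2⁷ labelings each);
100 seeds of n = 10,000 F2s for model selection.

## Known limitations

Single transcript per gene; canonical GT/AG sites only (no splice-strength
model); no NMD rule; F2 bulks only (no RIL/backcross types, no G′
statistic); no read-level or sequencing-error simulation; no linkage between
markers beyond the QTL-conditional model; a single pooled co-expression
network per species; no tree inference or divergence dating.  These are
boundaries of scope, not planned work.
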