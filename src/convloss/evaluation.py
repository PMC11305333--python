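"""Study-condition benchmarks: run each analysis stage against generator truth.

Each function here sets up the synthetic study conditions once, runs the
corresponding analysis end to end, and measures recovery of the planted
ground truth.  The acceptance checks and the reproduction script both call
these, so the measured quantities are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

from . import bsa, coexpression, comparative, lof, segregation, simulate
from .models import EffectClass


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Allele fixture
# ---------------------------------------------------------------------------

def load_pl_allele_table() -> pd.DataFrame:
    """Packaged (synthetic-reconstruction) PL loss-allele survey table."""
    with resources.files("convloss.data").joinpath("pl_alleles_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def pl_allele_counts() -> dict:
    table = load_pl_allele_table()
    return {
        "collapsed": comparative.count_distinct_alleles(table, collapse_shared=True),
        "per_species": comparative.count_distinct_alleles(table, collapse_shared=False),
        "n_rows": len(table),
    }


# ---------------------------------------------------------------------------
# LOF classification vs translate-the-mutant oracle
# ---------------------------------------------------------------------------

#: Requested class mix totalling 1000 variants.
DEFAULT_VARIANT_SPEC = [
    ("splice_donor", 100),
    ("splice_acceptor", 100),
    ("frameshift_indel", 200),
    ("stop_gained", 150),
    ("large_exonic_deletion", 50),
    ("inframe_indel", 100),
    ("missense", 100),
    ("synonymous", 100),
    ("intronic", 50),
    ("intergenic", 50),
]


@dataclass
class OracleReport:
    n_variants: int
    n_skipped: int
    lof_agreement: float
    truth_class_agreement: float
    mismatches: list[str]


def lof_oracle_benchmark(seed: int = 1, variant_spec=None) -> OracleReport:
    """Compare cascade LOF flags against the translation oracle.

    The oracle calls a variant LOF when the mutant protein is shorter than
    90% of wild type (splice variants are evaluated through intron-retention
    mis-splicing, since the splice defect itself does not change the coding
    sequence).  Mismatches are returned, not hidden.
    """
    spec = variant_spec or DEFAULT_VARIANT_SPEC
    s_genome, s_genes, s_var = _child_seeds(seed, 3)
    genome = simulate.gen_genome(2, 600_000, s_genome)
    annotation = simulate.gen_gene_models(
        genome,
        n_genes=60,
        exon_count_range=(2, 6),
        exon_len_range=(120, 420),
        intron_len_range=(60, 300),
        seed=s_genes,
    )
    variants, truth = simulate.inject_variants(genome, annotation, spec, seed=s_var)
    truth_by_id = {vid: (cls, flag) for vid, cls, flag in truth.variant_truth}

    wt_cache: dict[str, str] = {}
    n_agree = 0
    n_class = 0
    mismatches = []
    for var in variants:
        gene = annotation.locate(var.chrom, var.pos0, lof.GENE_FLANK)
        call = lof.classify_variant(gene, var, genome)
        intended_cls, _ = truth_by_id[var.variant_id]
        if call.effect_class is intended_cls:
            n_class += 1
        if gene is None:
            oracle_lof = False
        else:
            if gene.gene_id not in wt_cache:
                _, wt_cache[gene.gene_id] = lof.splice_and_translate(gene, genome, [])
            wt = wt_cache[gene.gene_id]
            if call.effect_class in (EffectClass.SPLICE_DONOR, EffectClass.SPLICE_ACCEPTOR):
                ti = _hit_intron_tx_index(gene, var)
                _, mis_call = lof.simulate_missplice(gene, genome, ti)
                oracle_lof = mis_call.truncation_fraction > 0.1 or (
                    mis_call.effect_class is EffectClass.FRAMESHIFT
                )
            else:
                _, mut = lof.splice_and_translate(gene, genome, [var])
                oracle_lof = len(mut) < 0.9 * len(wt)
        if oracle_lof == call.lof_flag:
            n_agree += 1
        else:
            mismatches.append(
                f"{var.variant_id} {call.effect_class.value} lof={call.lof_flag} oracle={oracle_lof}"
            )
    n = len(variants)
    return OracleReport(
        n_variants=n,
        n_skipped=len(truth.skipped),
        lof_agreement=n_agree / n,
        truth_class_agreement=n_class / n,
        mismatches=mismatches,
    )


def _hit_intron_tx_index(gene, var) -> int:
    for ti, donor, acceptor in gene.splice_windows():
        for win in (donor, acceptor):
            if win[0] <= var.pos0 < win[1]:
                return ti
    raise ValueError(f"{var.variant_id}: not at a splice window")


# ---------------------------------------------------------------------------
# BSA QTL recovery
# ---------------------------------------------------------------------------

@dataclass
class BsaRecoveryReport:
    n_runs: int
    recovery_rate: float
    median_interval_width: float
    delta_at_qtl: float


def bsa_recovery_benchmark(
    n_runs: int = 50,
    seed: int = 1,
    chrom_len: int = 50_000_000,
    n_high: int = 20,
    n_low: int = 20,
    depth: int = 50,
    n_snps: int = 2000,
    window: int = 2_000_000,
    step: int = 50_000,
    alpha: float = 0.01,
    min_run: int = 5,
    merge_gap: int = 2,
    min_depth: int = 10,
) -> BsaRecoveryReport:
    """Seeded BSA simulations: does the top called interval cover the QTL?

    Also reports the mean per-SNP delta within 250 kb of the planted QTL,
    whose analytic expectation at zero recombination is 2/3 for these bulks.
    """
    seeds = _child_seeds(seed, n_runs + 2)
    rng = np.random.default_rng(seeds[-1])
    band = bsa.null_ci([depth], n_high, n_low, n_sim=5000, alpha=alpha, seed=seeds[-2])
    ci_high = band[depth][1]
    hits = 0
    widths = []
    near_deltas = []
    for i in range(n_runs):
        qtl = int(rng.integers(0, chrom_len))
        counts, truth = simulate.gen_bsa_counts(
            chrom_len, qtl, n_high, n_low, depth, n_snps, seed=seeds[i]
        )
        snp = bsa.compute_delta_index(counts, min_depth=min_depth)
        near = snp[(snp["pos"] - qtl).abs() <= 250_000]
        if len(near):
            near_deltas.append(float(near["delta"].mean()))
        profile = bsa.smooth_profile(snp, window, step, chrom_len=chrom_len)
        intervals = bsa.call_intervals(profile, ci_high, min_run=min_run, merge_gap=merge_gap)
        if not intervals:
            continue
        top = max(intervals, key=lambda iv: iv.peak_delta)
        widths.append(top.end - top.start)
        if top.start <= truth.qtl_position < top.end:
            hits += 1
    return BsaRecoveryReport(
        n_runs=n_runs,
        recovery_rate=hits / n_runs,
        median_interval_width=float(np.median(widths)) if widths else float("nan"),
        delta_at_qtl=float(np.mean(near_deltas)) if near_deltas else float("nan"),
    )


# ---------------------------------------------------------------------------
# Co-expression conservation recovery
# ---------------------------------------------------------------------------

@dataclass
class ConservationReport:
    conserved_mean_auroc: float
    n_pairs_scored: int
    permuted_mean_auroc: float
    n_permutations: int


def conservation_benchmark(
    seed: int = 1,
    rho: float = 1.0,
    noise_sd: float = 0.1,
    n_genes: int = 200,
    n_samples: int = 500,
    n_modules: int = 20,
    k: int = 10,
    n_pairs: int = 25,
    n_perm: int = 100,
) -> ConservationReport:
    """AUROC of module-conserved ortholog pairs, plus a permutation null.

    The permutation null shuffles the species-B side of the orthology map
    and rescores a fixed focal pair; its mean should sit at chance (0.5).
    """
    cfg = simulate.ExpressionSimConfig(
        n_genes_per_species=n_genes,
        n_samples=n_samples,
        n_modules=n_modules,
        rho=rho,
        noise_sd=noise_sd,
        seed=seed,
    )
    pair, orthology, truth = simulate.gen_expression_pair(cfg)
    net_a = coexpression.build_network(pair.expr_a)
    net_b = coexpression.build_network(pair.expr_b)
    conserved = [
        (ga, gb)
        for ga, gb in zip(orthology["gene_a"], orthology["gene_b"])
        if truth.extras["conserved"].get(ga, False)
    ]
    rng = np.random.default_rng(seed)
    take = min(n_pairs, len(conserved))
    idx = rng.choice(len(conserved), size=take, replace=False)
    aurocs = []
    for i in idx:
        ga, gb = conserved[i]
        sc = coexpression.cross_species_auroc(net_a, net_b, orthology, ga, gb, k=k)
        if sc.auroc is not None:
            aurocs.append(sc.auroc)

    ga0, gb0 = conserved[0]
    perm_scores = []
    gb_col = orthology["gene_b"].to_numpy()
    for _ in range(n_perm):
        perm = orthology.copy()
        perm["gene_b"] = rng.permutation(gb_col)
        sc = coexpression.cross_species_auroc(net_a, net_b, perm, ga0, gb0, k=k)
        if sc.auroc is not None:
            perm_scores.append(sc.auroc)
    return ConservationReport(
        conserved_mean_auroc=float(np.mean(aurocs)),
        n_pairs_scored=len(aurocs),
        permuted_mean_auroc=float(np.mean(perm_scores)),
        n_permutations=len(perm_scores),
    )


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def brute_force_min_changes(tree, traits: dict) -> int:
    """Exhaustive small-parsimony oracle: minimise state changes over all
    ancestral labelings (2^internal nodes)."""
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(data=str(tree), schema="newick")
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    best = None
    for states in product((0, 1), repeat=len(internals)):
        assign = {id(nd): s for nd, s in zip(internals, states)}
        for lf in leaves:
            assign[id(lf)] = int(traits[lf.taxon.label])
        changes = sum(
            1
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and assign[id(nd)] != assign[id(nd.parent_node)]
        )
        best = changes if best is None else min(best, changes)
    return best


@dataclass
class ParsimonyReport:
    n_trees: int
    fitch_matches: int
    dollo_planted: int
    dollo_recovered: int


def parsimony_benchmark(
    n_trees: int = 100, n_taxa: int = 8, seed: int = 1, planted_losses: int = 5
) -> ParsimonyReport:
    """Fitch vs exhaustive minimisation on random trees; Dollo vs planted truth."""
    seeds = _child_seeds(seed, n_trees + 1)
    rng = np.random.default_rng(seeds[-1])
    matches = 0
    for i in range(n_trees):
        tree = simulate._random_topology(np.random.default_rng(seeds[i]), n_taxa)
        traits = {
            lf.taxon.label: int(rng.integers(0, 2)) for lf in tree.leaf_node_iter()
        }
        if comparative.fitch_count(tree, traits) == brute_force_min_changes(tree, traits):
            matches += 1
    tree, traits, truth = simulate.gen_tree_with_losses(24, planted_losses, seed=seed)
    recovered = comparative.min_independent_origins(tree, traits, mode="dollo_loss")
    return ParsimonyReport(
        n_trees=n_trees,
        fitch_matches=matches,
        dollo_planted=truth.loss_events,
        dollo_recovered=recovered,
    )


# ---------------------------------------------------------------------------
# Segregation model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionReport:
    n_seeds: int
    n_correct: int
    selection_rate: float


def model_selection_benchmark(
    n_seeds: int = 100, n: int = 10_000, seed: int = 1
) -> ModelSelectionReport:
    """Fraction of duplicate-recessive F2 simulations where 9:7 is selected."""
    seeds = _child_seeds(seed, n_seeds)
    correct = 0
    for s in seeds:
        pop = simulate.gen_f2_population("duplicate_recessive", n=n, seed=s)
        if segregation.fit_segregation_model(pop).best == "9:7":
            correct += 1
    return ModelSelectionReport(
        n_seeds=n_seeds, n_correct=correct, selection_rate=correct / n_seeds
    )
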