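"""Config-driven orchestration of the full synthetic study.

``run_pipeline`` executes simulate -> classify -> segregate -> map -> score
conservation -> count losses against one global seed, writing every stage
artifact, a MANIFEST of checksums, the resolved configuration, and a single
deterministic ``summary.json``.  The global seed fans out to per-stage child
seeds through :class:`numpy.random.SeedSequence`, so stages are individually
reproducible; completed stages are skipped on rerun when their artifacts'
checksums still match the manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, coexpression, comparative, io, lof, segregation, simulate
from .evaluation import load_pl_allele_table

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "lof_classify",
    "segregation",
    "bsa_qtlseq",
    "coexp_conservation",
    "comparative",
]

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "convloss_run",
    "verbosity": "info",
    "genome": {"n_chrom": 1, "chrom_len": 400_000},
    "genes": {"n_genes": 20, "exon_count_range": [2, 6], "exon_len_range": [120, 420]},
    "variants": {
        "spec": [
            ["splice_donor", 4],
            ["splice_acceptor", 4],
            ["frameshift_indel", 8],
            ["stop_gained", 6],
            ["large_exonic_deletion", 2],
            ["inframe_indel", 4],
            ["missense", 6],
            ["synonymous", 6],
            ["intronic", 5],
            ["intergenic", 5],
        ],
        "large_del_threshold": 50,
    },
    "f2": {"model": "single_recessive", "n": 2000, "distortion": 0.0, "penetrance": 1.0},
    "bsa": {
        "chrom_len": 20_000_000,
        "qtl_position": 12_000_000,
        "n_high_bulk": 30,
        "n_low_bulk": 30,
        "depth": 80,
        "n_snps": 1200,
        "window": 1_000_000,
        "step": 50_000,
        "alpha": 0.01,
        "min_run": 5,
        "min_depth": 10,
    },
    "expression": {
        "n_genes_per_species": 120,
        "n_samples": 200,
        "n_modules": 12,
        "rho": 1.0,
        "noise_sd": 0.1,
        "k": 10,
        "family_size": 3,
    },
    "tree": {"n_taxa": 24, "n_loss_events": 5},
}


def _validate(config: dict, defaults: dict, path="config") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in config.items():
        if key not in defaults:
            raise ValueError(f"unknown {path} key {key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"{path}.{key} must be a mapping")
            merged[key] = _validate(value, defaults[key], f"{path}.{key}")
        else:
            merged[key] = value
    return merged


def load_config(path_or_dict) -> dict:
    """Validate a run configuration (YAML path or dict) against the schema."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    return _validate(raw, DEFAULT_CONFIG)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "stages").mkdir(exist_ok=True)
        self.manifest_path = self.out / "MANIFEST.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        seqs = np.random.SeedSequence(config["seed"]).spawn(len(STAGES))
        self.stage_seeds = {
            name: int(s.generate_state(1)[0] % 2**31) for name, s in zip(STAGES, seqs)
        }

    def stage_fresh(self, name: str, outputs: list[str]) -> bool:
        summary = self.out / "stages" / f"{name}.json"
        if not summary.exists():
            return False
        for rel in outputs:
            p = self.out / rel
            if not p.exists() or self.manifest.get(rel) != _sha256(p):
                return False
        return True

    def record(self, name: str, outputs: list[str], summary: dict) -> dict:
        for rel in outputs:
            self.manifest[rel] = _sha256(self.out / rel)
        (self.out / "stages" / f"{name}.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1)
        )
        self.manifest_path.write_text(json.dumps(self.manifest, sort_keys=True, indent=1))
        return summary

    def load_summary(self, name: str) -> dict:
        return json.loads((self.out / "stages" / f"{name}.json").read_text())


def run_pipeline(config=None, out_dir=None, resume: bool = True) -> dict:
    """Run the full synthetic study and return the summary report.

    ``config`` may be a YAML path, a (possibly partial) dict merged over the
    defaults, or None for the default demo run.  A stage failure raises with
    the stage name; downstream stages are not attempted.
    """
    config = load_config(config or {})
    out = Path(out_dir or config["out_dir"])
    run = _Run(config, out)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    report: dict = {"seed": config["seed"], "stages": {}}
    state: dict = {}
    for name in STAGES:
        fn = _STAGE_FUNCS[name]
        # the simulate stage is always re-executed (deterministic and cheap)
        # to rebuild in-memory state; analysis stages resume from matching
        # checksummed artifacts
        if resume and name != "simulate" and run.stage_fresh(name, _STAGE_OUTPUTS[name]):
            summary = run.load_summary(name)
            log.info("stage %s resumed from artifacts", name)
        else:
            try:
                summary = fn(run, config, state)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = summary
        log.info("stage %s done", name)

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run, config: dict, state: dict) -> dict:
    seed = run.stage_seeds["simulate"]
    outputs = [
        "genome.fa", "genes.gff3", "variants.vcf", "population.tsv",
        "bsa_counts.tsv", "expression_a.tsv", "expression_b.tsv",
        "orthology.tsv", "tree.nwk", "traits.tsv", "truth.json",
    ]
    sub = np.random.SeedSequence(seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in sub]

    genome = simulate.gen_genome(seed=seeds[0], **config["genome"])
    gcfg = config["genes"]
    annotation = simulate.gen_gene_models(
        genome,
        n_genes=gcfg["n_genes"],
        exon_count_range=tuple(gcfg["exon_count_range"]),
        exon_len_range=tuple(gcfg["exon_len_range"]),
        seed=seeds[1],
    )
    vcfg = config["variants"]
    variants, vtruth = simulate.inject_variants(
        genome, annotation, [tuple(x) for x in vcfg["spec"]], seed=seeds[2],
        large_del_threshold=vcfg["large_del_threshold"],
    )
    pop = simulate.gen_f2_population(seed=seeds[3], **config["f2"])
    bcfg = config["bsa"]
    counts, btruth = simulate.gen_bsa_counts(
        bcfg["chrom_len"], bcfg["qtl_position"], bcfg["n_high_bulk"], bcfg["n_low_bulk"],
        bcfg["depth"], bcfg["n_snps"], seed=seeds[4],
    )
    ecfg = config["expression"]
    expr_cfg = simulate.ExpressionSimConfig(
        n_genes_per_species=ecfg["n_genes_per_species"],
        n_samples=ecfg["n_samples"],
        n_modules=ecfg["n_modules"],
        rho=ecfg["rho"],
        noise_sd=ecfg["noise_sd"],
        seed=seeds[5],
    )
    pair, orthology, etruth = simulate.gen_expression_pair(expr_cfg)
    tcfg = config["tree"]
    tree, traits, ttruth = simulate.gen_tree_with_losses(
        tcfg["n_taxa"], tcfg["n_loss_events"], seed=seeds[5]
    )

    io.write_fasta(genome, run.out / "genome.fa", seed=seed)
    io.write_gff3(annotation, run.out / "genes.gff3", seed=seed)
    io.write_vcf(variants, run.out / "variants.vcf", genome=genome, seed=seed)
    io.write_tsv(pop, run.out / "population.tsv", seed=seed)
    io.write_tsv(counts, run.out / "bsa_counts.tsv", seed=seed)
    io.write_tsv(pair.expr_a, run.out / "expression_a.tsv", seed=seed, index=True)
    io.write_tsv(pair.expr_b, run.out / "expression_b.tsv", seed=seed, index=True)
    io.write_tsv(orthology, run.out / "orthology.tsv", seed=seed)
    io.write_newick(tree, run.out / "tree.nwk")
    io.write_traits(traits, run.out / "traits.tsv", seed=seed)
    truth_payload = {
        "variant_truth": [
            [vid, cls.value, flag] for vid, cls, flag in vtruth.variant_truth
        ],
        "qtl_position": btruth.qtl_position,
        "loss_events": ttruth.loss_events,
        "conservation_rho": etruth.conservation_rho,
        "conserved_orthologs": etruth.extras["conserved"],
    }
    (run.out / "truth.json").write_text(json.dumps(truth_payload, sort_keys=True, indent=1))

    state.update(
        genome=genome, annotation=annotation, variants=variants, vtruth=vtruth,
        pop=pop, counts=counts, btruth=btruth, pair=pair, orthology=orthology,
        etruth=etruth, tree=tree, traits=traits, ttruth=ttruth,
    )
    return run.record(
        "simulate", outputs,
        {
            "n_genes": len(annotation),
            "n_variants": len(variants),
            "n_individuals": len(pop),
            "n_snps": len(counts),
            "n_taxa": tcfg["n_taxa"],
        },
    )


def _stage_lof(run: _Run, config: dict, state: dict) -> dict:
    calls = lof.classify_all(
        state["annotation"], state["variants"], state["genome"],
        config["variants"]["large_del_threshold"],
    )
    io.write_effects_tsv(calls, run.out / "effects.tsv", seed=run.stage_seeds["lof_classify"])
    io.write_vcf(
        state["variants"], run.out / "variants.annotated.vcf", genome=state["genome"],
        effects={c.variant_id: c for c in calls}, seed=run.stage_seeds["lof_classify"],
    )
    truth = {vid: (cls, flag) for vid, cls, flag in state["vtruth"].variant_truth}
    n_match = sum(
        1 for c in calls if truth.get(c.variant_id, (None, None))[0] is c.effect_class
    )
    return run.record(
        "lof_classify",
        ["effects.tsv", "variants.annotated.vcf"],
        {
            "n_classified": len(calls),
            "n_lof": sum(c.lof_flag for c in calls),
            "truth_class_agreement": round(n_match / len(calls), 4) if calls else None,
        },
    )


def _stage_segregation(run: _Run, config: dict, state: dict) -> dict:
    pop = state["pop"]
    report = segregation.test_cosegregation(pop, "pl")
    fit = segregation.fit_segregation_model(pop)
    payload = {
        "recessive_consistent": bool(report.recessive_consistent),
        "n_violations": len(report.violations),
        "phenotype_chi2": round(report.chi2_result.statistic, 4),
        "phenotype_p": round(report.chi2_result.p, 4),
        "distortion_p": round(report.distortion_result.p, 4),
        "best_model": fit.best,
        "model_p": {k: round(v.p, 4) for k, v in fit.results.items()},
    }
    (run.out / "segregation.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
    return run.record("segregation", ["segregation.json"], payload)


def _stage_bsa(run: _Run, config: dict, state: dict) -> dict:
    bcfg = config["bsa"]
    snp = bsa.compute_delta_index(state["counts"], min_depth=bcfg["min_depth"])
    profile = bsa.smooth_profile(
        snp, bcfg["window"], bcfg["step"], chrom_len=bcfg["chrom_len"]
    )
    band = bsa.null_ci(
        [bcfg["depth"]], bcfg["n_high_bulk"], bcfg["n_low_bulk"],
        n_sim=5000, alpha=bcfg["alpha"], seed=run.stage_seeds["bsa_qtlseq"],
    )
    intervals = bsa.call_intervals(profile, band[bcfg["depth"]][1], min_run=bcfg["min_run"])
    io.write_tsv(profile, run.out / "bsa_profile.tsv", seed=run.stage_seeds["bsa_qtlseq"])
    bsa.intervals_to_bed(intervals, run.out / "bsa_intervals.bed")
    qtl = state["btruth"].qtl_position
    top = max(intervals, key=lambda iv: iv.peak_delta) if intervals else None
    payload = {
        "n_snps_used": len(snp),
        "ci_high": round(band[bcfg["depth"]][1], 4),
        "n_intervals": len(intervals),
        "qtl_truth": qtl,
        "top_interval": [top.chrom, top.start, top.end] if top else None,
        "top_contains_truth": bool(top and top.start <= qtl < top.end),
        "peak_delta": round(top.peak_delta, 4) if top else None,
    }
    return run.record("bsa_qtlseq", ["bsa_profile.tsv", "bsa_intervals.bed"], payload)


def _stage_coexp(run: _Run, config: dict, state: dict) -> dict:
    ecfg = config["expression"]
    pair, orthology = state["pair"], state["orthology"]
    net_a = coexpression.build_network(pair.expr_a)
    net_b = coexpression.build_network(pair.expr_b)
    conserved = [
        (ga, gb)
        for ga, gb in zip(orthology["gene_a"], orthology["gene_b"])
        if state["etruth"].extras["conserved"].get(ga, False)
    ]
    fam = conserved[: ecfg["family_size"]]
    mat, _ = coexpression.family_auroc_matrix(
        net_a, net_b, orthology, [p[0] for p in fam], [p[1] for p in fam], k=ecfg["k"]
    )
    io.write_tsv(mat, run.out / "coexp_auroc.tsv", seed=run.stage_seeds["coexp_conservation"], index=True)
    diag = [mat.loc[ga, gb] for ga, gb in fam]
    payload = {
        "family_size": len(fam),
        "mean_matched_auroc": round(float(np.nanmean(diag)), 4),
        "k": ecfg["k"],
    }
    return run.record("coexp_conservation", ["coexp_auroc.tsv"], payload)


def _stage_comparative(run: _Run, config: dict, state: dict) -> dict:
    tree, traits = state["tree"], state["traits"]
    dollo = comparative.min_independent_origins(tree, traits, mode="dollo_loss")
    fitch = comparative.min_independent_origins(tree, traits, mode="fitch")
    alleles = load_pl_allele_table()
    n_collapsed = comparative.count_distinct_alleles(alleles, collapse_shared=True)
    genes = [g.gene_id for g in state["annotation"]]
    synteny = comparative.synteny_chain(genes, genes, [(g, g) for g in genes])
    payload = {
        "dollo_losses": dollo,
        "fitch_changes": fitch,
        "planted_losses": state["ttruth"].loss_events,
        "distinct_pl_alleles_collapsed": int(n_collapsed),
        "synteny_retention": round(synteny.retention, 4),
    }
    (run.out / "comparative.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
    return run.record("comparative", ["comparative.json"], payload)


_STAGE_OUTPUTS = {
    "simulate": [
        "genome.fa", "genes.gff3", "variants.vcf", "population.tsv", "bsa_counts.tsv",
        "expression_a.tsv", "expression_b.tsv", "orthology.tsv", "tree.nwk",
        "traits.tsv", "truth.json",
    ],
    "lof_classify": ["effects.tsv", "variants.annotated.vcf"],
    "segregation": ["segregation.json"],
    "bsa_qtlseq": ["bsa_profile.tsv", "bsa_intervals.bed"],
    "coexp_conservation": ["coexp_auroc.tsv"],
    "comparative": ["comparative.json"],
}

_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "lof_classify": _stage_lof,
    "segregation": _stage_segregation,
    "bsa_qtlseq": _stage_bsa,
    "coexp_conservation": _stage_coexp,
    "comparative": _stage_comparative,
}
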