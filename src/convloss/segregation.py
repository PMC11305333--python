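"""Mendelian segregation statistics for F2 populations.

Goodness-of-fit against classical two-class ratios (3:1 single recessive,
9:7 duplicate recessive, 13:3, 15:1), genotype-phenotype co-segregation with
recessive-consistency checking, and segregation-distortion testing of
genotype counts against 1:2:1.  No continuity correction is applied anywhere:
the uncorrected Pearson statistic is what reproduces printed pairs such as
chi-square 0.52 (df=1) -> p = 0.47.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("hom_ref", "het", "hom_alt")

#: Candidate F2 phenotype-ratio models as (present:absent ratio, n_loci).
SEGREGATION_MODELS = {
    "3:1": ((3, 1), 1),
    "9:7": ((9, 7), 2),
    "13:3": ((13, 3), 2),
    "15:1": ((15, 1), 2),
}

MODEL_LABELS = {
    "3:1": "single recessive",
    "9:7": "duplicate recessive",
    "13:3": "dominant suppression",
    "15:1": "duplicate dominant",
}


@dataclass
class SegregationTestResult:
    statistic: float
    df: int
    p: float
    observed: list[int]
    expected: list[float]
    model_label: str


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability (regularized incomplete gamma)."""
    if stat < 0:
        raise ValueError("statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(stat, df))


def chisq_gof(observed, expected_ratio, model_label: str = "") -> SegregationTestResult:
    """Pearson chi-square goodness of fit against an integer ratio.

    ``df = cells - 1``; no continuity correction.  Any expected cell below 1
    raises with advice to pool classes.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and ratio must have the same length")
    if obs.sum() <= 0:
        raise ValueError("observed counts sum to zero")
    if np.any(ratio <= 0):
        raise ValueError("ratio parts must be positive")
    expected = ratio / ratio.sum() * obs.sum()
    if np.any(expected < 1):
        raise ValueError(
            "expected count below 1; pool sparse classes before testing"
        )
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return SegregationTestResult(
        statistic=statistic,
        df=df,
        p=chisq_pvalue(statistic, df),
        observed=[int(x) for x in obs],
        expected=expected.tolist(),
        model_label=model_label or ":".join(str(int(r)) for r in ratio),
    )


def _phenotype_counts(pop: pd.DataFrame) -> tuple[int, int]:
    present = int((pop["phenotype"] == "trait_present").sum())
    absent = int((pop["phenotype"] == "trait_absent").sum())
    return present, absent


@dataclass
class CosegregationReport:
    recessive_consistent: bool
    violations: list[str]
    n_missing: int
    chi2_result: SegregationTestResult
    distortion_result: SegregationTestResult


def test_cosegregation(
    pop: pd.DataFrame, locus: str, penetrance_tolerance: int = 0
) -> CosegregationReport:
    """Test whether homozygosity at ``locus`` co-segregates with the trait.

    ``recessive_consistent`` is True iff (up to ``penetrance_tolerance``
    violating individuals) every trait-absent individual is ``hom_alt`` and
    every trait-present individual is not.  Missing genotypes are excluded
    pairwise and counted, never imputed.  ``chi2_result`` tests phenotype
    counts against 3:1; ``distortion_result`` tests genotype counts against
    1:2:1 (df = 2).
    """
    col = f"geno_{locus}"
    if col not in pop.columns:
        raise KeyError(f"locus {locus!r} not in population table")
    known = pop[pop[col] != "missing"]
    if known.empty:
        raise ValueError(f"locus {locus!r}: all genotypes missing")
    n_missing = len(pop) - len(known)
    absent_not_hom = known[(known["phenotype"] == "trait_absent") & (known[col] != "hom_alt")]
    present_hom = known[(known["phenotype"] == "trait_present") & (known[col] == "hom_alt")]
    violations = list(absent_not_hom["individual_id"]) + list(present_hom["individual_id"])
    geno_counts = [int((known[col] == g).sum()) for g in GENOTYPES]
    present, absent = _phenotype_counts(known)
    return CosegregationReport(
        recessive_consistent=len(violations) <= penetrance_tolerance,
        violations=violations,
        n_missing=n_missing,
        chi2_result=chisq_gof([present, absent], (3, 1), "3:1"),
        distortion_result=chisq_gof(geno_counts, (1, 2, 1), "1:2:1"),
    )


@dataclass
class ModelFit:
    best: str
    results: dict[str, SegregationTestResult] = field(default_factory=dict)


def fit_segregation_model(pop_or_counts) -> ModelFit:
    """Rank candidate F2 phenotype-ratio models by chi-square p-value.

    Accepts a population table or a ``(present, absent)`` count pair.  Ties
    are broken toward models with fewer loci.  Requires n >= 16 so the 15:1
    expectation stays above one count.
    """
    if isinstance(pop_or_counts, pd.DataFrame):
        counts = _phenotype_counts(pop_or_counts)
    else:
        counts = tuple(int(x) for x in pop_or_counts)
    n = sum(counts)
    if n < 16:
        raise ValueError("need at least 16 individuals for model selection")
    results = {
        name: chisq_gof(counts, ratio, name)
        for name, (ratio, _) in SEGREGATION_MODELS.items()
    }
    best = min(results, key=lambda name: (-results[name].p, SEGREGATION_MODELS[name][1]))
    return ModelFit(best=best, results=results)
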