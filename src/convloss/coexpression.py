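"""Cross-species co-expression conservation scoring.

Rank-standardized Spearman co-expression networks, ortholog-mapped
neighbor-voting AUROC (how well one gene's co-expression ranking in species
B recovers the orthologs of its partner's top co-expression neighbors in
species A), family-by-family AUROC matrices, and the tau tissue-specificity
index.

Spearman correlation is used throughout: it is invariant to monotone
transforms of expression, which is what makes the scores testable and robust
across heterogeneous meta-analysis samples.  Undefined scores are explicit
nulls (``auroc is None``), never silently 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr


@dataclass
class CoexpressionNetwork:
    """Gene-by-gene rank-standardized co-expression matrix.

    Each row is a gene's ranked similarity to every other gene, scaled to
    (0, 1] with mid-rank tie handling; self-similarity is the row maximum.
    Constant-expression genes are flagged and excluded from neighbor sets.
    """

    matrix: pd.DataFrame
    excluded: frozenset

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def row(self, gene: str) -> pd.Series:
        return self.matrix.loc[gene]


@dataclass
class ConservationScore:
    gene_pair: tuple[str, str]
    auroc: float | None
    n_positives: int
    n_candidates: int
    k_used: int
    reason: str = ""


@dataclass
class TissueSpecificityScore:
    gene_id: str
    tau: float | None
    tissue_means: pd.Series
    reason: str = ""


def build_network(expr: pd.DataFrame) -> CoexpressionNetwork:
    """Spearman co-expression network with per-row rank standardization."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples per species")
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    values = expr.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    excluded = frozenset(expr.index[constant])
    if expr.shape[0] == 1:
        corr = np.ones((1, 1))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr, _ = spearmanr(values.T)
        corr = np.atleast_2d(corr)
    n = expr.shape[0]
    ranked = np.full((n, n), np.nan)
    valid = ~constant
    vidx = np.nonzero(valid)[0]
    for i in vidx:
        row = corr[i, vidx].astype(float)
        # self-similarity is the maximum possible correlation; a perfect
        # correlate mid-rank-ties with it, sharing the row maximum
        row[np.searchsorted(vidx, i)] = 1.0
        ranked[i, vidx] = rankdata(row) / len(vidx)
    mat = pd.DataFrame(ranked, index=expr.index, columns=expr.index)
    return CoexpressionNetwork(matrix=mat, excluded=excluded)


def _ortholog_maps(orthology: pd.DataFrame):
    a2b: dict[str, set] = {}
    b_with_orth: set = set()
    for ga, gb in zip(orthology["gene_a"], orthology["gene_b"]):
        a2b.setdefault(ga, set()).add(gb)
        b_with_orth.add(gb)
    return a2b, b_with_orth


def top_neighbors(net: CoexpressionNetwork, gene: str, k: int) -> list[str]:
    """Top-k co-expression neighbors of ``gene`` (self and flagged genes excluded).

    Ties beyond rank k are broken by gene order in the matrix.
    """
    row = net.row(gene).drop(index=[gene], errors="ignore")
    row = row.drop(index=[g for g in net.excluded if g in row.index])
    row = row.dropna()
    return list(row.nlargest(k).index)


def cross_species_auroc(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthology: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    k: int = 10,
) -> ConservationScore:
    """Neighbor-voting AUROC for one cross-species gene pair.

    Positives are the species-B orthologs of ``gene_a``'s top-k species-A
    co-expression neighbors (neighbors without B-orthologs are dropped;
    many-to-many orthologs expand the positive set).  Candidates are all
    species-B genes having at least one A-ortholog, minus ``gene_b`` itself.
    ``gene_b``'s network row ranks the candidates; AUROC uses the rank-sum
    (Mann-Whitney) formula with mid-rank ties.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gene_a not in net_a.matrix.index:
        raise KeyError(gene_a)
    if gene_b not in net_b.matrix.index:
        raise KeyError(gene_b)
    a2b, b_with_orth = _ortholog_maps(orthology)
    neighbors = top_neighbors(net_a, gene_a, k)
    positives = set()
    for nb in neighbors:
        positives |= a2b.get(nb, set())
    scores = net_b.row(gene_b)
    candidates = [
        g for g in net_b.genes
        if g in b_with_orth and g != gene_b and not np.isnan(scores[g])
    ]
    positives &= set(candidates)
    pair = (gene_a, gene_b)
    if not positives:
        return ConservationScore(pair, None, 0, len(candidates), k, reason="empty positive set")
    if len(positives) == len(candidates):
        return ConservationScore(
            pair, None, len(positives), len(candidates), k, reason="no negatives"
        )
    vals = scores[candidates].to_numpy(dtype=float)
    ranks = rankdata(vals)
    is_pos = np.array([g in positives for g in candidates])
    n_pos = int(is_pos.sum())
    n_neg = len(candidates) - n_pos
    auroc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ConservationScore(pair, float(auroc), n_pos, len(candidates), k)


def family_auroc_matrix(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthology: pd.DataFrame,
    family_a,
    family_b,
    k: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """AUROC matrix over a gene family's cross-species pairs.

    Returns ``(matrix, scores)`` where the matrix holds AUROCs (NaN for
    undefined cells) with family-A rows and family-B columns, and ``scores``
    maps pairs to full :class:`ConservationScore` records.
    """
    family_a, family_b = list(family_a), list(family_b)
    if not family_a or not family_b:
        raise ValueError("families must be non-empty")
    scores = {}
    mat = pd.DataFrame(np.nan, index=family_a, columns=family_b)
    for ga in family_a:
        for gb in family_b:
            sc = cross_species_auroc(net_a, net_b, orthology, ga, gb, k=k)
            scores[(ga, gb)] = sc
            if sc.auroc is not None:
                mat.loc[ga, gb] = sc.auroc
    return mat, scores


def tissue_specificity(
    expr: pd.DataFrame, tissue_labels: pd.Series
) -> list[TissueSpecificityScore]:
    """Tau tissue-specificity index per gene.

    Per-tissue mean expression is log2(x+1)-scaled, then
    ``tau = sum_i (1 - x_i / max_i x_i) / (N_tissues - 1)``: 0 for uniform
    expression, 1 for single-tissue expression.  All-zero genes get a null
    tau with a reason.
    """
    labels = tissue_labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a tissue label")
    tissues = labels.unique()
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    means = expr.T.groupby(labels).mean().T  # genes x tissues
    scaled = np.log2(means + 1.0)
    out = []
    n_t = len(tissues)
    for gene in expr.index:
        x = scaled.loc[gene]
        mx = x.max()
        if mx == 0:
            out.append(
                TissueSpecificityScore(gene, None, means.loc[gene], reason="all-zero gene")
            )
            continue
        tau = float(((1 - x / mx).sum()) / (n_t - 1))
        out.append(TissueSpecificityScore(gene, tau, means.loc[gene]))
    return out
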