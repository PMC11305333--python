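"""Phylogenetic loss counting, allele-based lower bounds, synteny chaining.

``min_independent_origins`` counts minimum trait changes on a rooted tree
either by unconstrained Fitch small parsimony or under a Dollo loss model
(root fixed at trait-present, re-gain forbidden), where the count equals the
number of maximal all-absent leaf clades.  ``count_distinct_alleles`` turns
an allele survey table into a lower bound on independent origins, optionally
collapsing identical mutations shared between species.  ``synteny_chain``
finds collinear anchor blocks between two loci via longest
strictly-increasing (or decreasing) subsequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _resolve_polytomies(tree: dendropy.Tree) -> bool:
    """Left-branching deterministic resolution; returns True if any resolved."""
    resolved = False
    for nd in list(tree.preorder_node_iter()):
        while len(nd.child_nodes()) > 2:
            resolved = True
            children = nd.child_nodes()
            a, b = children[0], children[1]
            nd.remove_child(a)
            nd.remove_child(b)
            joint = dendropy.Node()
            joint.add_child(a)
            joint.add_child(b)
            nd.insert_child(0, joint)
    return resolved


def _leaf_state(nd, traits) -> int:
    label = nd.taxon.label if nd.taxon is not None else None
    if label is None or label not in traits:
        raise ValueError(f"leaf {label!r} missing a trait state")
    state = int(traits[label])
    if state not in (0, 1):
        raise ValueError(f"leaf {label}: state must be 0 or 1")
    return state


def fitch_count(tree, traits: dict) -> int:
    """Minimum number of state changes (both directions allowed)."""
    tree = _as_tree(tree)
    _resolve_polytomies(tree)
    changes = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.state_set = frozenset({_leaf_state(nd, traits)})
        else:
            sets = [c.state_set for c in nd.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                nd.state_set = inter
            else:
                nd.state_set = frozenset.union(*sets)
                changes += 1
    return changes


def dollo_loss_count(tree, traits: dict) -> int:
    """Minimum 1->0 transitions with the root fixed at 1 and no re-gain.

    Equals the number of maximal all-absent leaf clades.
    """
    tree = _as_tree(tree)
    losses = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.all_absent = _leaf_state(nd, traits) == 0
        else:
            nd.all_absent = all(c.all_absent for c in nd.child_nodes())
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        if nd.all_absent and (parent is None or not parent.all_absent):
            losses += 1
    return losses


def min_independent_origins(tree, traits: dict, mode: str = "dollo_loss") -> int:
    """Count independent trait transitions on a rooted binary trait tree.

    ``mode='fitch'`` is unconstrained small parsimony (a lower bound when the
    input had polytomies, which are resolved deterministically first);
    ``mode='dollo_loss'`` counts irreversible losses from a trait-present
    root.
    """
    if mode == "fitch":
        return fitch_count(tree, traits)
    if mode == "dollo_loss":
        return dollo_loss_count(tree, traits)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Allele tables
# ---------------------------------------------------------------------------

REQUIRED_ALLELE_COLUMNS = ("species", "gene", "effect_class", "position_key")


def canonical_descriptor(row) -> tuple[str, str, str]:
    """Canonical mutation key: (ortholog gene id, effect class, CDS-relative
    position key), whitespace-stripped and case-folded so the same allele
    detected in two species compares equal."""
    try:
        return (
            str(row["gene"]).strip().lower(),
            str(row["effect_class"]).strip().lower(),
            str(row["position_key"]).strip().lower(),
        )
    except KeyError as exc:
        raise ValueError(f"malformed allele descriptor: missing {exc}") from exc


def count_distinct_alleles(table: pd.DataFrame, collapse_shared: bool = True) -> int:
    """Number of distinct loss alleles in a survey table.

    With ``collapse_shared`` identical descriptors found in several species
    count once — a conservative lower bound on independent origins; without
    it every (species, allele) observation counts.
    """
    if table.empty:
        raise ValueError("allele table is empty")
    for col in REQUIRED_ALLELE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"allele table missing column {col!r}")
    if table[list(REQUIRED_ALLELE_COLUMNS)].isna().any().any():
        raise ValueError("malformed allele descriptor: null field")
    descriptors = [canonical_descriptor(row) for _, row in table.iterrows()]
    if collapse_shared:
        return len(set(descriptors))
    species = table["species"].astype(str).str.strip()
    return len({(sp, d) for sp, d in zip(species, descriptors)})


# ---------------------------------------------------------------------------
# Synteny chaining
# ---------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    orientation: str  # '+' or '-'
    anchors: list[tuple[str, str]]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyResult:
    blocks: list[SyntenyBlock]
    retention: float
    n_anchors: int


def _lis_indices(seq: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence (O(n^2) DP)."""
    n = len(seq)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def synteny_chain(
    locus_a: list[str],
    locus_b: list[str],
    anchors: list[tuple[str, str]],
    min_block: int = 3,
) -> SyntenyResult:
    """Maximal collinear anchor chains between two ordered gene lists.

    Anchors are mapped to index pairs, sorted by locus-A order, and chained
    by longest strictly increasing (orientation ``+``) or decreasing (``-``)
    subsequence of locus-B indices.  The longer chain is the primary block;
    blocks shorter than ``min_block`` anchors are discarded.  Retention is
    the fraction of anchors captured by the reported blocks' best chain.
    """
    if not anchors:
        raise ValueError("need at least one anchor pair")
    ia = {g: i for i, g in enumerate(locus_a)}
    ib = {g: i for i, g in enumerate(locus_b)}
    for ga, gb in anchors:
        if ga not in ia:
            raise KeyError(f"anchor gene {ga!r} not in locus A")
        if gb not in ib:
            raise KeyError(f"anchor gene {gb!r} not in locus B")
    pairs = sorted(((ia[ga], ib[gb], ga, gb) for ga, gb in anchors))
    b_seq = [p[1] for p in pairs]
    inc = _lis_indices(b_seq)
    dec = _lis_indices([-x for x in b_seq])
    chains = []
    for idxs, orient in ((inc, "+"), (dec, "-")):
        if len(idxs) >= min_block:
            chains.append(
                SyntenyBlock(orient, [(pairs[i][2], pairs[i][3]) for i in idxs])
            )
    chains.sort(key=lambda b: -b.n_anchors)
    retention = (chains[0].n_anchors / len(anchors)) if chains else 0.0
    return SyntenyResult(blocks=chains, retention=retention, n_anchors=len(anchors))
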