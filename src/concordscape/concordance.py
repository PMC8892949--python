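"""Gene and site concordance factors per internal branch of a reference tree.

gCF for a branch is the percentage of *decisive* gene trees (those containing
at least one taxon from each of the four subtrees adjacent to the branch)
whose own split set contains the branch's bipartition, restricted to the taxa
shared with that gene tree.  sCF is the mean, over quartets sampled around
the branch (one taxon per adjacent subtree), of the percentage of decisive
sites whose pattern supports the branch's pairing of the quartet; with no
phylogenetic signal it sits at the 1/3 chance expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo_core import (
    Bipartition,
    MultipleAlignment,
    Node,
    PhyloError,
    PhyloTree,
    _clade_sets,
    unrooted_splits,
)


@dataclass(frozen=True)
class BranchQuadripartition:
    """The four taxon sets of the subtrees incident to an internal branch.

    ``sets[0]`` and ``sets[1]`` hang off one endpoint, ``sets[2]`` and
    ``sets[3]`` off the other, so the branch's bipartition is
    (sets[0] | sets[1]) vs (sets[2] | sets[3]).
    """

    sets: tuple[frozenset, frozenset, frozenset, frozenset]

    def __post_init__(self):
        if len(self.sets) != 4 or any(not s for s in self.sets):
            raise PhyloError("quadripartition needs four nonempty sets")
        for a, b in itertools.combinations(self.sets, 2):
            if a & b:
                raise PhyloError("quadripartition sets must be disjoint")

    @property
    def bipartition(self) -> Bipartition:
        return Bipartition(self.sets[0] | self.sets[1],
                           self.sets[2] | self.sets[3])

    @property
    def taxa(self) -> frozenset:
        return frozenset().union(*self.sets)


@dataclass
class BranchConcordanceRecord:
    branch_id: int
    bipartition: Bipartition
    gCF: float | None      # percent; None when no decisive gene tree
    gCF_N: int             # concordant decisive gene trees
    gN: int                # decisive gene trees
    sCF: float | None      # percent; None when no retained quartet
    sN: float | None       # mean decisive sites per retained quartet
    quartets_sampled: int
    seed: int | None = None

    def as_row(self) -> dict:
        fmt = lambda v: "NA" if v is None else round(v, 4)
        return {
            "branch_id": self.branch_id,
            "bipartition": repr(self.bipartition),
            "gCF": fmt(self.gCF),
            "gCF_N": self.gCF_N,
            "gN": self.gN,
            "sCF": fmt(self.sCF),
            "sN": fmt(self.sN),
            "quartets": self.quartets_sampled,
        }


# ---------------------------------------------------------------------------
# Quadripartition geometry
# ---------------------------------------------------------------------------

def quadripartition(tree: PhyloTree, branch_child: Node) -> BranchQuadripartition:
    """Quadripartition around the branch above ``branch_child``.

    The branch is treated on the unrooted version of the tree; terminal
    branches (either endpoint contributing fewer than two subtrees) raise.
    """
    if branch_child.is_leaf or branch_child.parent is None:
        raise PhyloError("quadripartition is defined for internal branches only")
    if len(branch_child.children) != 2:
        raise PhyloError("tree must be binary at the branch endpoints")
    clades = _clade_sets(tree)
    taxa = tree.taxon_set()
    below = tuple(clades[c] for c in branch_child.children)
    parent = branch_child.parent
    siblings = [c for c in parent.children if c is not branch_child]
    if parent is tree.root and len(parent.children) == 2:
        # unrooted view: the other endpoint is the sibling's top node
        sib = siblings[0]
        if sib.is_leaf or len(sib.children) != 2:
            if sib.is_leaf:
                raise PhyloError("branch is terminal on the unrooted tree")
            raise PhyloError("tree must be binary at the branch endpoints")
        above = tuple(clades[c] for c in sib.children)
    elif parent is tree.root:
        if len(siblings) != 2:
            raise PhyloError("tree must be binary at the branch endpoints")
        above = tuple(clades[s] for s in siblings)
    else:
        if len(siblings) != 1:
            raise PhyloError("tree must be binary at the branch endpoints")
        rest = taxa - clades[parent]
        if not rest:
            raise PhyloError("branch is terminal on the unrooted tree")
        above = (clades[siblings[0]], rest)
    return BranchQuadripartition((below[0], below[1], above[0], above[1]))


def internal_branches(tree: PhyloTree) -> list[tuple[Node, BranchQuadripartition]]:
    """The distinct internal branches of the unrooted tree, with quadripartitions.

    Returns one entry per unrooted internal branch (n-3 for a binary tree on
    n leaves); the two root-adjacent edges of a rooted tree collapse to one.
    """
    out = []
    seen: set[Bipartition] = set()
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        try:
            quad = quadripartition(tree, node)
        except PhyloError:
            continue
        bip = quad.bipartition
        if bip in seen:
            continue
        seen.add(bip)
        out.append((node, quad))
    return out


# ---------------------------------------------------------------------------
# Gene concordance
# ---------------------------------------------------------------------------

class GeneTreeIndex:
    """Precomputed taxon set and normalized split set of one gene tree."""

    __slots__ = ("taxa", "splits")

    def __init__(self, tree: PhyloTree):
        self.taxa = tree.taxon_set()
        self.splits = unrooted_splits(tree)

    def contains(self, bipartition: Bipartition) -> bool:
        """Does this gene tree contain the bipartition restricted to its taxa?"""
        a = bipartition.side_a & self.taxa
        b = bipartition.side_b & self.taxa
        if len(a) < 2 or len(b) < 2:
            return False
        anchor = min(self.taxa)
        side = a if anchor in a else b
        return side in self.splits


def index_gene_trees(gene_trees: Sequence) -> list[GeneTreeIndex]:
    return [g if isinstance(g, GeneTreeIndex) else GeneTreeIndex(g)
            for g in gene_trees]


def gene_concordance(branch_quad: BranchQuadripartition,
                     gene_trees: Sequence) -> tuple[float | None, int, int]:
    """(gCF, concordant count, decisive count) for one branch.

    A gene tree is decisive iff it contains at least one taxon from each of
    the four adjacent subtrees; a decisive tree is concordant iff its split
    set (restricted to shared taxa) contains the branch's bipartition.  gCF
    is None (not 0) when no gene tree is decisive.
    """
    indices = index_gene_trees(gene_trees)
    bip = branch_quad.bipartition
    g_n = 0
    g_cf_n = 0
    for idx in indices:
        if not all(s & idx.taxa for s in branch_quad.sets):
            continue
        g_n += 1
        if idx.contains(bip):
            g_cf_n += 1
    gcf = 100.0 * g_cf_n / g_n if g_n > 0 else None
    return gcf, g_cf_n, g_n


# ---------------------------------------------------------------------------
# Site concordance
# ---------------------------------------------------------------------------

def site_support(alignment: MultipleAlignment,
                 quartet: Sequence[str]) -> tuple[int, int, int, int]:
    """Classify every site of the alignment for one quartet of taxa.

    The quartet is ordered (one member of each quadripartition set); a site
    is decisive iff all four characters are unambiguous nucleotides and the
    pattern is a clean binary xxyy / xyxy / xyyx.  Returns
    (s1, s2, s3, decisive) where s1 counts sites pairing taxa 1+2 vs 3+4
    (the reference branch's arrangement), s2 pairs 1+3, s3 pairs 1+4.
    """
    if len(set(quartet)) != 4:
        raise PhyloError("quartet must be four distinct taxa")
    rows = [alignment.codes[alignment.row_index(t)] for t in quartet]
    a, b, c, d = rows
    valid = (a < 4) & (b < 4) & (c < 4) & (d < 4)
    s1 = int(np.count_nonzero(valid & (a == b) & (c == d) & (a != c)))
    s2 = int(np.count_nonzero(valid & (a == c) & (b == d) & (a != b)))
    s3 = int(np.count_nonzero(valid & (a == d) & (b == c) & (a != b)))
    return s1, s2, s3, s1 + s2 + s3


def _quartet_choices(branch_quad: BranchQuadripartition,
                     alignment: MultipleAlignment,
                     n_quartets: int,
                     rng: np.random.Generator) -> list[tuple[str, ...]]:
    present = []
    aln_taxa = set(alignment.taxa)
    for s in branch_quad.sets:
        members = sorted(s & aln_taxa)
        if not members:
            raise PhyloError("a quadripartition set has no taxon in the alignment")
        present.append(members)
    n_comb = int(np.prod([len(m) for m in present]))
    if n_comb <= n_quartets:
        return list(itertools.product(*present))
    return [tuple(m[rng.integers(len(m))] for m in present)
            for _ in range(n_quartets)]


def site_concordance(branch_quad: BranchQuadripartition,
                     alignment: MultipleAlignment,
                     n_quartets: int = 100,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[float | None, float | None, int]:
    """(sCF, mean decisive sites, quartets sampled) for one branch.

    Quartets with one taxon per adjacent subtree are sampled uniformly with
    replacement (or enumerated exhaustively when there are at most
    ``n_quartets`` combinations); quartets with zero decisive sites are
    excluded from the mean rather than scored 0.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    quartets = _quartet_choices(branch_quad, alignment, n_quartets, rng)
    props = []
    decisive = []
    for q in quartets:
        s1, _, _, total = site_support(alignment, q)
        if total == 0:
            continue
        props.append(100.0 * s1 / total)
        decisive.append(total)
    if not props:
        return None, None, len(quartets)
    return float(np.mean(props)), float(np.mean(decisive)), len(quartets)


# ---------------------------------------------------------------------------
# Per-tree report
# ---------------------------------------------------------------------------

def concordance_table(ref_tree: PhyloTree,
                      gene_trees: Sequence,
                      alignment: MultipleAlignment | None = None,
                      n_quartets: int = 100,
                      seed: int = 0) -> list[BranchConcordanceRecord]:
    """gCF/sCF records for every internal branch of ``ref_tree``.

    Deterministic given ``seed``: each branch draws its quartets from an
    independent child stream of a single seed sequence, so records do not
    depend on evaluation order.
    """
    indices = index_gene_trees(gene_trees)
    branches = internal_branches(ref_tree)
    streams = np.random.SeedSequence(seed).spawn(len(branches))
    records = []
    for b_id, ((_, quad), stream) in enumerate(zip(branches, streams)):
        gcf, gcf_n, g_n = gene_concordance(quad, indices)
        if alignment is not None:
            scf, s_n, n_q = site_concordance(
                quad, alignment, n_quartets, np.random.default_rng(stream)
            )
        else:
            scf, s_n, n_q = None, None, 0
        records.append(BranchConcordanceRecord(
            branch_id=b_id, bipartition=quad.bipartition,
            gCF=gcf, gCF_N=gcf_n, gN=g_n,
            sCF=scf, sN=s_n, quartets_sampled=n_q, seed=seed,
        ))
    return records


def concordance_frame(records: Sequence[BranchConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def write_concordance_table(records: Sequence[BranchConcordanceRecord],
                            path) -> None:
    concordance_frame(records).to_csv(path, sep="\t", index=False)


def annotate_tree(ref_tree: PhyloTree,
                  records: Sequence[BranchConcordanceRecord]) -> PhyloTree:
    """Copy of the reference tree with internal labels 'gCF/sCF' (NA for undefined)."""
    by_bip = {r.bipartition: r for r in records}
    tree = ref_tree.copy()
    for node, quad in internal_branches(tree):
        rec = by_bip.get(quad.bipartition)
        if rec is None:
            continue
        g = "NA" if rec.gCF is None else f"{rec.gCF:.1f}"
        s = "NA" if rec.sCF is None else f"{rec.sCF:.1f}"
        node.label = f"{g}/{s}"
    return tree
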