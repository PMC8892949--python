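"""Concordance landscapes over every arrangement of named clades.

The scan enumerates all rooted binary arrangements of the ingroup clades
((2k-3)!! of them; 105 for five clades), re-evaluates gene and site
concordance on the clade-level branches of each arrangement against the same
gene trees and supermatrix, and summarizes each arrangement by its mean gCF
and sCF over the branches that actually vary between arrangements (the
ingroup/outgroup split and all within-clade structure are shared by every
arrangement and are excluded).  The arrangements are then embedded in 2-D by
principal coordinates on their pairwise Robinson--Foulds distances, giving a
map of treespace in which concordance hotspots can be read off.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .concordance import (
    BranchConcordanceRecord,
    BranchQuadripartition,
    GeneTreeIndex,
    gene_concordance,
    index_gene_trees,
    site_concordance,
)
from .phylo_core import (
    Bipartition,
    CladeMap,
    MultipleAlignment,
    PhyloError,
    PhyloTree,
    canonical_form,
    enumerate_rooted_topologies,
    rooted_clades,
)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class TopologyRecord:
    topology_id: str
    skeleton: PhyloTree                  # rooted tree over ingroup clade labels
    canonical: str
    branch_records: list                 # BranchConcordanceRecord per scanned branch
    mean_gCF: float
    mean_sCF: float


@dataclass
class Landscape:
    records: list
    rf_matrix: np.ndarray
    coordinates: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    clade_map: CladeMap | None = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.records):
            row = {
                "topology_id": rec.topology_id,
                "canonical_newick": rec.canonical,
                "mean_gCF": round(rec.mean_gCF, 4),
                "mean_sCF": round(rec.mean_sCF, 4),
            }
            if self.coordinates is not None:
                row["coord1"] = round(float(self.coordinates[i, 0]), 6)
                row["coord2"] = round(float(self.coordinates[i, 1]), 6)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BipartitionSummary:
    clade_set: frozenset                 # ingroup clade labels forming the clade
    entries: list                        # (topology_id, gCF, sCF) tuples
    n_topologies: int


# ---------------------------------------------------------------------------
# Topology IDs
# ---------------------------------------------------------------------------

def topology_ids(n: int, seed: int | None = None) -> list[str]:
    """Two-letter IDs aa, ab, ... in order; optionally seeded-shuffled."""
    letters = string.ascii_lowercase
    ids = ["".join(p) for p in itertools.product(letters, repeat=2)][:n]
    if len(ids) < n:
        raise PhyloError("more than 676 topologies; widen the ID scheme")
    if seed is not None:
        rng = np.random.default_rng(seed)
        ids = list(rng.permutation(ids))
    return ids


# ---------------------------------------------------------------------------
# Clade-level geometry
# ---------------------------------------------------------------------------

def _scanned_branches(skeleton: PhyloTree, clade_map: CladeMap,
                      ) -> list[tuple[frozenset, BranchQuadripartition]]:
    """Clade-level internal branches of one arrangement, as full-taxon quads.

    The skeleton is rooted over the ingroup clades; with the outgroup
    attached at its root, every internal clade of the skeleton (k-2 of them)
    is a branch whose presence varies between arrangements.  Each is expanded
    to a quadripartition by pooling member taxa: the clade's two child
    subtrees below, and the sibling subtree plus everything else (remaining
    ingroup + outgroup) above.
    """
    taxa_of = {c: clade_map.taxa_in(c) for c in clade_map.clades}
    for clade, taxa in taxa_of.items():
        if not taxa:
            raise PhyloError(f"clade {clade!r} has no taxa")
    all_taxa = clade_map.taxa()

    def pool(labels) -> frozenset:
        return frozenset().union(*(taxa_of[l] for l in labels))

    clades_below: dict = {}
    for node in skeleton.postorder():
        if node.is_leaf:
            clades_below[node] = frozenset([node.label])
        else:
            clades_below[node] = frozenset().union(
                *(clades_below[c] for c in node.children))

    out = []
    for node in skeleton.postorder():
        if node.is_leaf or node is skeleton.root:
            continue
        c1, c2 = node.children
        sibling = [c for c in node.parent.children if c is not node][0]
        below1, below2 = pool(clades_below[c1]), pool(clades_below[c2])
        sib_taxa = pool(clades_below[sibling])
        rest = all_taxa - below1 - below2 - sib_taxa
        quad = BranchQuadripartition((below1, below2, sib_taxa, rest))
        out.append((frozenset(clades_below[node]), quad))
    return out


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def scan_landscape(gene_trees: Sequence,
                   alignment: MultipleAlignment | None,
                   clade_map: CladeMap,
                   n_quartets: int = 100,
                   seed: int = 0,
                   embed: bool = True,
                   shuffle_ids: bool = False) -> Landscape:
    """Concordance factors for every rooted arrangement of the ingroup clades.

    gCF depends only on a branch's bipartition, so it is computed once per
    distinct clade-level bipartition and shared across arrangements; sCF is
    recomputed per arrangement branch (its quadripartition context and
    quartet sample differ), with a seed stream per (arrangement, branch) so
    results are deterministic and order-independent.
    """
    indices = index_gene_trees(gene_trees)
    observed = frozenset().union(*(idx.taxa for idx in indices)) \
        if indices else frozenset()
    if alignment is not None:
        observed = observed | frozenset(alignment.taxa)
    for clade in clade_map.clades:
        if not clade_map.taxa_in(clade) & observed:
            raise PhyloError(f"clade {clade!r} has no taxon in the data")
    ingroup = clade_map.ingroup_clades
    skeletons = enumerate_rooted_topologies(ingroup)
    ids = topology_ids(len(skeletons), seed=seed if shuffle_ids else None)

    gcf_cache: dict = {}
    records = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(skeletons))
    for topo_i, (skeleton, topo_id) in enumerate(zip(skeletons, ids)):
        branches = _scanned_branches(skeleton, clade_map)
        branch_streams = streams[topo_i].spawn(len(branches))
        branch_records = []
        for b_id, ((clade_set, quad), stream) in enumerate(
                zip(branches, branch_streams)):
            bip = quad.bipartition
            if bip not in gcf_cache:
                gcf_cache[bip] = gene_concordance(quad, indices)
            gcf, gcf_n, g_n = gcf_cache[bip]
            if alignment is not None:
                scf, s_n, n_q = site_concordance(
                    quad, alignment, n_quartets,
                    np.random.default_rng(stream))
            else:
                scf, s_n, n_q = None, None, 0
            branch_records.append(BranchConcordanceRecord(
                branch_id=b_id, bipartition=bip, gCF=gcf, gCF_N=gcf_n,
                gN=g_n, sCF=scf, sN=s_n, quartets_sampled=n_q, seed=seed,
            ))
        gcfs = [r.gCF for r in branch_records if r.gCF is not None]
        scfs = [r.sCF for r in branch_records if r.sCF is not None]
        records.append(TopologyRecord(
            topology_id=topo_id,
            skeleton=skeleton,
            canonical=canonical_form(skeleton),
            branch_records=branch_records,
            mean_gCF=float(np.mean(gcfs)) if gcfs else float("nan"),
            mean_sCF=float(np.mean(scfs)) if scfs else float("nan"),
        ))

    n = len(records)
    rf = np.zeros((n, n), dtype=int)
    bip_sets = [rooted_clades(r.skeleton) for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            rf[i, j] = rf[j, i] = len(bip_sets[i] ^ bip_sets[j])
    landscape = Landscape(records, rf, clade_map=clade_map)
    if embed:
        coords, eigvals = embed_treespace(landscape)
        landscape.coordinates = coords
        landscape.eigenvalues = eigvals
    return landscape


# ---------------------------------------------------------------------------
# Bipartition-level summary
# ---------------------------------------------------------------------------

def bipartition_summary(landscape: Landscape) -> list[BipartitionSummary]:
    """Concordance per distinct clade-level rooted clade across arrangements.

    For k ingroup clades there are C(k,2)+...+C(k,k-1) distinct nontrivial
    clades (25 for k=5); a clade's gCF is identical in every arrangement
    containing it, while sCF varies with the quadripartition context, so the
    full (topology, gCF, sCF) distribution is reported.
    """
    by_clade: dict = {}
    for rec in landscape.records:
        for br, (clade_set, _) in zip(
                rec.branch_records,
                _iter_skeleton_clades(rec.skeleton)):
            by_clade.setdefault(clade_set, []).append(
                (rec.topology_id, br.gCF, br.sCF))
    return [
        BipartitionSummary(clade_set=cs, entries=entries,
                           n_topologies=len(entries))
        for cs, entries in sorted(by_clade.items(), key=lambda kv: sorted(kv[0]))
    ]


def _iter_skeleton_clades(skeleton: PhyloTree):
    clades_below: dict = {}
    out = []
    for node in skeleton.postorder():
        if node.is_leaf:
            clades_below[node] = frozenset([node.label])
            continue
        clades_below[node] = frozenset().union(
            *(clades_below[c] for c in node.children))
        if node is not skeleton.root:
            out.append((clades_below[node], node))
    return out


def bipartition_frame(summaries: Sequence[BipartitionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for topo_id, gcf, scf in s.entries:
            rows.append({
                "clade": "+".join(sorted(s.clade_set)),
                "n_topologies": s.n_topologies,
                "topology_id": topo_id,
                "gCF": "NA" if gcf is None else round(gcf, 4),
                "sCF": "NA" if scf is None else round(scf, 4),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Treespace embedding
# ---------------------------------------------------------------------------

def embed_treespace(landscape: Landscape) -> tuple[np.ndarray, np.ndarray]:
    """Classical MDS (principal coordinates) of the RF matrix.

    Negative eigenvalues are truncated to zero; the first two axes are
    returned with the full eigenvalue spectrum.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive, which makes the
    embedding reproducible up to the inherent reflection symmetry.
    """
    D = np.asarray(landscape.rf_matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise PhyloError("need at least three topologies to embed")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals_trunc = np.clip(eigvals, 0.0, None)
    coords = eigvecs[:, :2] * np.sqrt(eigvals_trunc[:2])
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords, eigvals_trunc


def plot_landscape(landscape: Landscape, path) -> None:
    """Treespace scatter: point size = mean gCF, color = mean sCF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = landscape.frame()
    fig, ax = plt.subplots(figsize=(7, 6))
    sc = ax.scatter(df["coord1"], df["coord2"],
                    s=(df["mean_gCF"].astype(float) + 1.0) * 3.0,
                    c=df["mean_sCF"].astype(float), cmap="viridis",
                    alpha=0.85, edgecolors="k", linewidths=0.3)
    best = df["mean_gCF"].astype(float).idxmax()
    ax.scatter([df.loc[best, "coord1"]], [df.loc[best, "coord2"]],
               facecolors="none", edgecolors="darkred", s=220, linewidths=1.5,
               label=f"max mean gCF ({df.loc[best, 'topology_id']})")
    fig.colorbar(sc, ax=ax, label="mean sCF (%)")
    ax.set_xlabel("PCoA axis 1 (RF distance)")
    ax.set_ylabel("PCoA axis 2 (RF distance)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Per-gene support classes and covariates
# ---------------------------------------------------------------------------

ARRANGEMENT_LABELS = ("arr1", "arr2", "arr3", "uninformative")


def classify_gene_support(gene_trees: Sequence,
                          focal_quad: BranchQuadripartition) -> list[str]:
    """Label each gene by the focal-quartet arrangement it supports.

    arr1 pairs sets 1+2 (the reference arrangement), arr2 pairs 1+3, arr3
    pairs 1+4; genes that are not decisive for the quadripartition, or that
    resolve none of the three pooled arrangements, are uninformative.
    """
    indices = index_gene_trees(gene_trees)
    s1, s2, s3, s4 = focal_quad.sets
    arrangements = [
        Bipartition(s1 | s2, s3 | s4),
        Bipartition(s1 | s3, s2 | s4),
        Bipartition(s1 | s4, s2 | s3),
    ]
    labels = []
    for idx in indices:
        if not all(s & idx.taxa for s in focal_quad.sets):
            labels.append("uninformative")
            continue
        for label, bip in zip(("arr1", "arr2", "arr3"), arrangements):
            if idx.contains(bip):
                labels.append(label)
                break
        else:
            labels.append("uninformative")
    return labels


def conservation_score(alignment: MultipleAlignment) -> float:
    """Mean over columns of mean pairwise identity among non-gap residues.

    A transparent stand-in for trimming-tool similarity scores: for each
    column, the fraction of identical pairs among rows with unambiguous
    nucleotides (columns with fewer than two such rows are skipped); the
    score is in [0, 1].
    """
    codes = alignment.codes
    scores = []
    for col in codes.T:
        obs = col[col < 4]
        if len(obs) < 2:
            continue
        counts = np.bincount(obs, minlength=4)
        n = len(obs)
        same = float((counts * (counts - 1)).sum()) / (n * (n - 1))
        scores.append(same)
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def covariate_summary(labels: Sequence[str],
                      gene_lengths: Sequence[float],
                      conservation_scores: Sequence[float],
                      alpha: float = 0.05) -> dict:
    """Per-class covariate statistics with pairwise rank-sum tests.

    Returns per-class medians/IQRs for gene length and conservation and
    Benjamini--Hochberg-adjusted Mann--Whitney p-values for each class pair;
    classes with fewer than two genes get descriptive statistics only.
    """
    df = pd.DataFrame({
        "label": list(labels),
        "length": np.asarray(gene_lengths, dtype=float),
        "conservation": np.asarray(conservation_scores, dtype=float),
    })
    groups = []
    for label, grp in df.groupby("label", sort=True):
        groups.append({
            "label": label,
            "n": len(grp),
            "length_median": float(grp["length"].median()),
            "length_iqr": float(grp["length"].quantile(0.75)
                                - grp["length"].quantile(0.25)),
            "conservation_median": float(grp["conservation"].median()),
            "conservation_iqr": float(grp["conservation"].quantile(0.75)
                                      - grp["conservation"].quantile(0.25)),
        })
    stats_frame = pd.DataFrame(groups)

    testable = [g["label"] for g in groups if g["n"] >= 2]
    skipped = [g["label"] for g in groups if g["n"] < 2]
    if skipped:
        import warnings

        warnings.warn(f"classes with < 2 genes skipped in tests: {skipped}")
    rows = []
    for var in ("length", "conservation"):
        for a, b in itertools.combinations(testable, 2):
            xa = df.loc[df["label"] == a, var]
            xb = df.loc[df["label"] == b, var]
            if xa.nunique() <= 1 and xb.nunique() <= 1 and \
                    set(xa.unique()) == set(xb.unique()):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xa, xb,
                                             alternative="two-sided").pvalue)
            rows.append({"variable": var, "class_a": a, "class_b": b,
                         "p_raw": p})
    tests = pd.DataFrame(
        rows, columns=["variable", "class_a", "class_b", "p_raw"])
    if len(tests):
        tests["p_adj"] = multipletests(tests["p_raw"], method="fdr_bh")[1]
        tests["significant"] = tests["p_adj"] < alpha
    return {"stats": stats_frame, "tests": tests}
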