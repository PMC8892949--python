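"""Quartet maximum likelihood, likelihood-mapping censuses, and the SOWH test.

The likelihood core is Felsenstein pruning over compressed site patterns
under JC69 (default) or GTR without rate heterogeneity.  Keeping the model
this small makes every quantity verifiable against closed forms, which is
what the likelihood-mapping census and the SOWH parametric bootstrap are
built on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .phylo_core import (
    MultipleAlignment,
    GenePartition,
    Node,
    PhyloError,
    PhyloTree,
    unroot,
)


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model: rate matrix Q and equilibrium freqs.

    Q is scaled so the expected substitution rate at equilibrium is 1, i.e.
    branch lengths are in expected substitutions per site.
    """

    name: str
    Q: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.allclose(self.Q.sum(axis=1), 0, atol=1e-10):
            raise PhyloError("rate matrix rows must sum to zero")
        if not np.isclose(self.freqs.sum(), 1.0):
            raise PhyloError("equilibrium frequencies must sum to one")


def jc69() -> SubstitutionModel:
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return SubstitutionModel("JC69", Q, np.full(4, 0.25))


def gtr(rates: Sequence[float], freqs: Sequence[float]) -> SubstitutionModel:
    """GTR from 6 exchangeabilities (AC, AG, AT, CG, CT, GT) and 4 frequencies."""
    rates = np.asarray(rates, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if rates.shape != (6,) or freqs.shape != (4,):
        raise PhyloError("GTR needs 6 exchangeabilities and 4 frequencies")
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for r, (i, j) in zip(rates, pairs):
        Q[i, j] = r * freqs[j]
        Q[j, i] = r * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(freqs * np.diag(Q))
    return SubstitutionModel("GTR", Q / scale, freqs)


def transition_probability(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); closed form for JC69, matrix exponential otherwise."""
    if t < 0:
        raise PhyloError("branch length must be nonnegative")
    if model.name == "JC69":
        e = np.exp(-4.0 * t / 3.0)
        p_same = 0.25 + 0.75 * e
        p_diff = 0.25 - 0.25 * e
        P = np.full((4, 4), p_diff)
        np.fill_diagonal(P, p_same)
        return P
    return expm(model.Q * t)


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Pruning likelihood for a fixed topology over compressed site patterns.

    Branch lengths are a flat vector (one entry per non-root node in
    preorder), so the same engine serves plain evaluation and cyclic
    branch-length optimization without rebuilding per call.
    """

    def __init__(self, tree: PhyloTree, alignment: MultipleAlignment,
                 model: SubstitutionModel):
        self.model = model
        self.nodes = list(tree.postorder())
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root = tree.root
        # branch parameter slots: every node except root
        self.branch_nodes = [n for n in self.nodes if n is not self.root]
        self.branch_slot = {id(n): i for i, n in enumerate(self.branch_nodes)}
        missing = [n.label for n in self.branch_nodes if n.length is None]
        self._tree_lengths = np.array(
            [n.length if n.length is not None else np.nan
             for n in self.branch_nodes]
        )
        self._missing = missing
        # compress site patterns over tree leaves
        leaf_nodes = [n for n in self.nodes if n.is_leaf]
        rows = []
        for n in leaf_nodes:
            try:
                rows.append(alignment.codes[alignment.row_index(n.label)])
            except PhyloError:
                raise PhyloError(
                    f"leaf {n.label!r} missing from alignment"
                ) from None
        mat = np.stack(rows)  # (n_leaves, n_sites)
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.weights = weights.astype(float)
        self.n_sites = alignment.n_sites
        npat = patterns.shape[1]
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # code 4 -> missing
        self.leaf_partials = {
            id(n): eye5[patterns[i]] for i, n in enumerate(leaf_nodes)
        }
        self._npat = npat

    def tree_lengths(self) -> np.ndarray:
        if self._missing:
            raise PhyloError(f"missing branch lengths above {self._missing}")
        return self._tree_lengths.copy()

    def loglik(self, lengths: np.ndarray) -> float:
        model = self.model
        jc = model.name == "JC69"
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self._npat)
        for node in self.nodes:
            if node.is_leaf:
                partials[id(node)] = self.leaf_partials[id(node)]
                continue
            prod = None
            for child in node.children:
                L = partials.pop(id(child))
                t = lengths[self.branch_slot[id(child)]]
                if jc:
                    e = np.exp(-4.0 * t / 3.0)
                    p_diff = 0.25 - 0.25 * e
                    row_sum = L.sum(axis=1, keepdims=True)
                    contrib = p_diff * row_sum + e * L  # p_same - p_diff = e
                else:
                    P = transition_probability(model, t)
                    contrib = L @ P.T
                prod = contrib if prod is None else prod * contrib
            mx = prod.max(axis=1)
            mx[mx == 0] = 1.0
            prod = prod / mx[:, None]
            logscale += np.log(mx)
            partials[id(node)] = prod
        root_partial = partials[id(self.root)]
        site_lik = root_partial @ model.freqs
        return float(np.dot(self.weights, np.log(site_lik) + logscale))


def pruning_loglik(tree: PhyloTree, alignment: MultipleAlignment,
                   model: SubstitutionModel | None = None) -> float:
    """Log-likelihood of the alignment on the tree (lengths taken from the tree)."""
    model = model or jc69()
    engine = PruningEngine(tree, alignment, model)
    return engine.loglik(engine.tree_lengths())


@dataclass
class BranchOptResult:
    tree: PhyloTree
    lengths: np.ndarray
    loglik: float
    converged: bool
    sweeps: int


def optimize_branch_lengths(topology: PhyloTree,
                            alignment: MultipleAlignment,
                            model: SubstitutionModel | None = None,
                            init: float = 0.1,
                            bounds: tuple[float, float] = (1e-8, 10.0),
                            tol: float = 1e-6,
                            max_sweeps: int = 100) -> BranchOptResult:
    """Cyclic per-branch ML branch lengths on a fixed topology.

    Each sweep optimizes every branch in turn with bounded scalar
    minimization; sweeps stop when the log-likelihood improves by less than
    ``tol``.  The ascent is monotone because each univariate step starts from
    the current optimum.
    """
    model = model or jc69()
    work = unroot(topology) if topology.rooted else topology.copy()
    engine = PruningEngine(work, alignment, model)
    lengths = np.full(len(engine.branch_nodes), float(init))
    lnl = engine.loglik(lengths)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        prev = lnl
        for slot in range(len(lengths)):
            current = lengths[slot]

            def neg(t, slot=slot):
                lengths[slot] = t
                return -engine.loglik(lengths)

            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun >= lnl:
                lengths[slot] = res.x
                lnl = -res.fun
            else:  # keep the previous value if the line search regressed
                lengths[slot] = current
        if lnl - prev < tol:
            converged = True
            break
    for node, t in zip(engine.branch_nodes, lengths):
        node.length = float(t)
    return BranchOptResult(work, lengths.copy(), lnl, converged, sweeps)


# ---------------------------------------------------------------------------
# Likelihood mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LmapPoint:
    """Barycentric likelihood weights for the three quartet arrangements."""

    p1: float
    p2: float
    p3: float

    def __post_init__(self):
        s = self.p1 + self.p2 + self.p3
        if not np.isclose(s, 1.0):
            raise PhyloError("barycentric weights must sum to one")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])


REGIONS = ("corner1", "corner2", "corner3", "side12", "side13", "side23",
           "center")
BASINS = ("basin1", "basin2", "basin3")


def classify_region(p: Sequence[float], dominance: float = 2.0) -> str:
    """Seven-region rule on the simplex: corners, sides, center.

    Corner i when p_i dominates both others by the dominance factor; side ij
    when p_i and p_j both dominate p_k; else center.  Ties resolve toward the
    lower-numbered region.
    """
    p1, p2, p3 = p
    d = dominance
    if p1 >= d * p2 and p1 >= d * p3:
        return "corner1"
    if p2 >= d * p1 and p2 >= d * p3:
        return "corner2"
    if p3 >= d * p1 and p3 >= d * p2:
        return "corner3"
    if p1 >= d * p3 and p2 >= d * p3:
        return "side12"
    if p1 >= d * p2 and p3 >= d * p2:
        return "side13"
    if p2 >= d * p1 and p3 >= d * p1:
        return "side23"
    return "center"


def _quartet_topologies(taxa: Sequence[str]) -> list[PhyloTree]:
    a, b, c, d = taxa
    out = []
    for pair in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
        x1, x2, y1, y2 = pair
        root = Node()
        inner = root.add_child(Node())
        inner.add_child(Node(label=x1))
        inner.add_child(Node(label=x2))
        root.add_child(Node(label=y1))
        root.add_child(Node(label=y2))
        out.append(PhyloTree(root, rooted=False))
    return out


def quartet_map_point(alignment4: MultipleAlignment,
                      model: SubstitutionModel | None = None,
                      dominance: float = 2.0,
                      ) -> tuple[LmapPoint, str, str]:
    """Score the three arrangements of a four-taxon alignment.

    Arrangement 1 pairs the first two taxa of the alignment; the weights are
    exp(lnL_i - max lnL) normalized to sum one, the basin is the argmax (ties
    to the lowest index), and the region follows the seven-way rule.
    """
    if alignment4.n_taxa != 4:
        raise PhyloError("likelihood mapping needs exactly four taxa")
    model = model or jc69()
    lnls = []
    for topo in _quartet_topologies(alignment4.taxa):
        res = optimize_branch_lengths(topo, alignment4, model)
        lnls.append(res.loglik)
    lnls = np.array(lnls)
    w = np.exp(lnls - lnls.max())
    p = w / w.sum()
    point = LmapPoint(*p)
    basin = BASINS[int(np.argmax(p))]
    region = classify_region(p, dominance)
    return point, region, basin


@dataclass
class LmapCensus:
    region_counts: dict = field(default_factory=lambda: {r: 0 for r in REGIONS})
    basin_counts: dict = field(default_factory=lambda: {b: 0 for b in BASINS})
    total: int = 0
    per_gene: list = field(default_factory=list)

    def add(self, gene: str, region: str, basin: str) -> None:
        self.region_counts[region] += 1
        self.basin_counts[basin] += 1
        self.total += 1
        self.per_gene.append({"gene": gene, "region": region, "basin": basin})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_gene)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"area": k, "count": v, "kind": "region"}
                for k, v in self.region_counts.items()]
        rows += [{"area": k, "count": v, "kind": "basin"}
                 for k, v in self.basin_counts.items()]
        rows.append({"area": "total", "count": self.total, "kind": "total"})
        return pd.DataFrame(rows)


def lmap_scan(alignment: MultipleAlignment,
              partitions: Sequence[GenePartition],
              groups: Sequence[Sequence[str]],
              model: SubstitutionModel | None = None,
              max_quartets_per_gene: int | None = None,
              dominance: float = 2.0,
              seed: int = 0) -> LmapCensus:
    """Likelihood-mapping census over genes for four taxon groups.

    For each gene, quartets take one taxon per group among taxa with data in
    that gene (all combinations by default, optionally capped by uniform
    subsampling); arrangement 1 is fixed as (group1+group2 | group3+group4).
    """
    model = model or jc69()
    if len(groups) != 4:
        raise PhyloError("likelihood mapping needs exactly four groups")
    groups = [list(g) for g in groups]
    flat = [t for g in groups for t in g]
    if len(set(flat)) != len(flat):
        raise PhyloError("groups must be disjoint")
    rng = np.random.default_rng(seed)
    census = LmapCensus()
    any_contrib = [False] * 4
    for part in partitions:
        sub = alignment.subset_columns(part.start, part.end)
        has_data = {
            t: bool((sub.codes[sub.row_index(t)] < 4).any())
            for t in sub.taxa
        }
        present = [[t for t in g if has_data.get(t, False)] for g in groups]
        if any(not p for p in present):
            continue
        for i in range(4):
            any_contrib[i] = True
        combos = list(itertools.product(*present))
        if max_quartets_per_gene is not None and len(combos) > max_quartets_per_gene:
            idx = rng.choice(len(combos), size=max_quartets_per_gene,
                             replace=False)
            combos = [combos[i] for i in sorted(idx)]
        for quartet in combos:
            sub4 = sub.subset_taxa(list(quartet))
            _, region, basin = quartet_map_point(sub4, model, dominance)
            census.add(part.name, region, basin)
    if not all(any_contrib):
        raise PhyloError("a group has no taxon with data in any gene")
    return census


# ---------------------------------------------------------------------------
# SOWH test
# ---------------------------------------------------------------------------

@dataclass
class SowhResult:
    delta_obs: float
    null_deltas: list[float]
    p_value: float
    n_reps: int
    seed: int
    identical_topologies: bool = False


def sowh_test(alignment: MultipleAlignment,
              topo_best: PhyloTree,
              topo_null: PhyloTree,
              model: SubstitutionModel | None = None,
              n_reps: int = 100,
              seed: int = 0) -> SowhResult:
    """Parametric-bootstrap (SOWH) comparison of two fixed topologies.

    delta = lnL(best) - lnL(null), both with branch lengths optimized on the
    observed data; the null distribution of delta comes from ``n_reps``
    alignments simulated under the null topology with its fitted lengths,
    re-optimizing both topologies per replicate.  The p-value uses the
    add-one estimator, so it is never exactly zero.
    """
    from . import synthetic_data  # local import: synthetic_data uses this module

    model = model or jc69()
    from .phylo_core import canonical_form

    if canonical_form(unroot(topo_best)) == canonical_form(unroot(topo_null)):
        import warnings

        warnings.warn("topologies are identical; SOWH delta is 0 and p = 1")
        return SowhResult(0.0, [0.0] * n_reps, 1.0, n_reps, seed, True)

    def delta(aln: MultipleAlignment) -> tuple[float, BranchOptResult]:
        best = optimize_branch_lengths(topo_best, aln, model)
        null = optimize_branch_lengths(topo_null, aln, model)
        return best.loglik - null.loglik, null

    delta_obs, null_fit = delta(alignment)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    null_deltas = []
    for stream in streams:
        sim = synthetic_data.simulate_sequences(
            null_fit.tree, alignment.n_sites, model=model,
            rng=np.random.default_rng(stream),
        )
        null_deltas.append(delta(sim)[0])
    exceed = sum(1 for d in null_deltas if d >= delta_obs)
    p = (1 + exceed) / (1 + n_reps)
    return SowhResult(delta_obs, null_deltas, p, n_reps, seed)
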