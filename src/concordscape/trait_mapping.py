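"""Discrete-trait layer: substrate classification, Mk fitting, stochastic maps.

Oviposition substrate is treated as a k-state character on a time-calibrated
tree.  Species are classified from rearing-record counts (generalist when two
substrates each exceed 1/4 of records, or none exceeds 2/3), an Mk model is
fitted by maximum likelihood, and full character histories are sampled
conditional on the tips: node states from the pruning partials, then
endpoint-conditioned paths along each branch by uniformization.  Transition
censuses and max-posterior node summaries are computed over the sampled maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo_core import Node, PhyloError, PhyloTree


SUBSTRATE_CATEGORIES = (
    "bark", "leaf", "sap", "fungus", "flower", "fruit", "spider egg mass",
    "generalist", "unknown",
)


# ---------------------------------------------------------------------------
# Substrate classification from rearing records
# ---------------------------------------------------------------------------

def classify_substrate(counts: Mapping[str, int]) -> str:
    """Specialist/generalist/unknown call from one species' rearing records.

    Generalist: any two substrates each with more than 1/4 of records, or no
    substrate with more than 2/3.  Otherwise the species is a specialist in
    the unique substrate exceeding 2/3.  No records at all -> unknown.
    """
    for cat, n in counts.items():
        if n < 0:
            raise PhyloError(f"negative rearing count for {cat!r}")
    total = sum(counts.values())
    if total == 0:
        return "unknown"
    fracs = sorted((n / total for n in counts.values()), reverse=True)
    over_quarter = sum(1 for f in fracs if f > 0.25)
    if over_quarter >= 2 or fracs[0] <= 2.0 / 3.0:
        return "generalist"
    top = max(counts, key=lambda c: counts[c])
    return top


def classify_rearing_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species substrate calls from a long table (species, substrate, count)."""
    required = {"species", "substrate", "count"}
    if not required.issubset(table.columns):
        raise PhyloError(f"rearing table needs columns {sorted(required)}")
    calls = []
    for species, grp in table.groupby("species", sort=True):
        counts = dict(zip(grp["substrate"], grp["count"].astype(int)))
        calls.append({"species": species, "call": classify_substrate(counts)})
    return pd.DataFrame(calls)


# ---------------------------------------------------------------------------
# Mk model
# ---------------------------------------------------------------------------

@dataclass
class MkModel:
    """Continuous-time Markov model for a discrete character.

    ``structure`` is ER (one rate), SYM (symmetric pairs), or ARD (all rates
    different); ``root_prior`` is 'flat' or 'stationary'.
    """

    states: tuple[str, ...]
    Q: np.ndarray
    structure: str = "ER"
    root_prior: str = "flat"

    def __post_init__(self):
        self.states = tuple(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise PhyloError("Q shape must match the state set")
        off = self.Q[~np.eye(k, dtype=bool)]
        if (off < -1e-12).any():
            raise PhyloError("off-diagonal rates must be nonnegative")
        if not np.allclose(self.Q.sum(axis=1), 0, atol=1e-9):
            raise PhyloError("Q rows must sum to zero")
        if self.structure not in ("ER", "SYM", "ARD"):
            raise PhyloError("structure must be ER, SYM, or ARD")

    @property
    def k(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise PhyloError(f"state {state!r} not in model states") from None

    def prior(self) -> np.ndarray:
        if self.root_prior == "flat":
            return np.full(self.k, 1.0 / self.k)
        # stationary distribution: left null vector of Q
        vals, vecs = np.linalg.eig(self.Q.T)
        i = int(np.argmin(np.abs(vals)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise PhyloError("branch length must be nonnegative")
        if self.structure == "ER" and self.k > 1:
            # closed form: all off-diagonal rates equal r
            r = float(self.Q[0, 1]) if self.k > 1 else 0.0
            k = self.k
            e = np.exp(-k * r * t)
            p_same = 1.0 / k + (k - 1.0) / k * e
            p_diff = 1.0 / k - 1.0 / k * e
            P = np.full((k, k), p_diff)
            np.fill_diagonal(P, p_same)
            return P
        return expm(self.Q * t)


def mk_er(states: Sequence[str], rate: float,
          root_prior: str = "flat") -> MkModel:
    k = len(states)
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -rate * (k - 1))
    return MkModel(tuple(states), Q, "ER", root_prior)


def _build_Q(states, structure, rates) -> np.ndarray:
    k = len(states)
    Q = np.zeros((k, k))
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    if structure == "ER":
        for i, j in pairs:
            Q[i, j] = rates[0]
    elif structure == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    else:  # ARD
        for r, (i, j) in zip(rates, pairs):
            Q[i, j] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def n_free_rates(k: int, structure: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _tip_partials(tree: PhyloTree, tip_states: Mapping[str, str],
                  model: MkModel) -> dict:
    partials = {}
    for leaf in tree.leaves():
        state = tip_states.get(leaf.label)
        vec = np.ones(model.k)
        if state is not None:
            vec = np.zeros(model.k)
            vec[model.state_index(state)] = 1.0
        partials[id(leaf)] = vec
    return partials


def _down_partials(tree: PhyloTree, tip_states: Mapping[str, str],
                   model: MkModel) -> tuple[dict, float]:
    """Per-node conditional likelihood vectors (scaled) and the log scale sum."""
    partials = _tip_partials(tree, tip_states, model)
    logscale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            continue
        vec = np.ones(model.k)
        for child in node.children:
            if child.length is None:
                raise PhyloError(f"missing branch length above {child.label!r}")
            P = model.transition_matrix(child.length)
            vec = vec * (P @ partials[id(child)])
        mx = vec.max()
        if mx <= 0:
            raise PhyloError("tip states have zero likelihood on this tree")
        vec = vec / mx
        logscale += np.log(mx)
        partials[id(node)] = vec
    return partials, logscale


def mk_loglik(tree: PhyloTree, tip_states: Mapping[str, str],
              model: MkModel) -> float:
    """Pruning log-likelihood of tip states; missing tips are uninformative."""
    partials, logscale = _down_partials(tree, tip_states, model)
    root_lik = float(partials[id(tree.root)] @ model.prior())
    return np.log(root_lik) + logscale


def fit_mk(tree: PhyloTree, tip_states: Mapping[str, str],
           states: Sequence[str] | None = None,
           structure: str = "ER",
           root_prior: str = "flat") -> MkModel:
    """Maximum-likelihood Mk rates (log-parameterized, bounded L-BFGS-B)."""
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    states = tuple(states)
    observed = set(tip_states.values())
    if len(observed) < 2:
        warnings.warn("fewer than two observed states; rate pinned near zero")
    n = n_free_rates(len(states), structure)

    def neg(log_rates):
        Q = _build_Q(states, structure, np.exp(log_rates))
        model = MkModel(states, Q, structure, root_prior)
        return -mk_loglik(tree, tip_states, model)

    # coarse log-grid on a shared rate locates the likelihood basin; the
    # surface saturates for fast rates, where gradient methods stall
    grid = np.log(np.array([1e-4, 1e-3, 1e-2, 0.05, 0.2, 0.8, 3.0, 12.0, 50.0]))
    grid_vals = [neg(np.full(n, g)) for g in grid]
    x0 = np.full(n, grid[int(np.argmin(grid_vals))])
    res = minimize(neg, x0, method="L-BFGS-B",
                   bounds=[(np.log(1e-8), np.log(1e3))] * n)
    best = res.x if res.fun <= neg(x0) else x0
    Q = _build_Q(states, structure, np.exp(best))
    return MkModel(states, Q, structure, root_prior)


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------

@dataclass
class CharacterHistory:
    """Piecewise-constant state path along every branch of one tree.

    ``branch_segments`` maps each non-root node (identifying the branch above
    it) to ordered (duration, state) segments running parent -> child;
    ``node_states`` maps every node to its sampled (or simulated) state.
    Node keys are the tree's :class:`Node` objects.
    """

    tree: PhyloTree
    node_states: dict
    branch_segments: dict

    def validate(self, tol: float = 1e-9) -> None:
        for node, segments in self.branch_segments.items():
            total = sum(d for d, _ in segments)
            if abs(total - (node.length or 0.0)) > tol:
                raise PhyloError("segment durations must sum to branch length")
            for (_, s1), (_, s2) in zip(segments, segments[1:]):
                if s1 == s2:
                    raise PhyloError("adjacent segments must differ in state")
            if segments[0][1] != self.node_states[node.parent]:
                raise PhyloError("first segment must match the parent state")
            if segments[-1][1] != self.node_states[node]:
                raise PhyloError("last segment must match the child state")

    def n_transitions(self) -> int:
        return sum(len(s) - 1 for s in self.branch_segments.values())


def _sample_path(i: int, j: int, t: float, model: MkModel,
                 rng: np.random.Generator, max_jumps: int = 500,
                 ) -> list[tuple[float, int]]:
    """Endpoint-conditioned path from state i to j over time t (uniformization)."""
    Q = model.Q
    mu = float(np.max(-np.diag(Q)))
    if mu == 0 or t == 0:
        if i != j:
            raise PhyloError("zero-rate process cannot connect distinct endpoints")
        return [(t, i)]
    R = np.eye(model.k) + Q / mu
    p_ij = model.transition_matrix(t)[i, j]
    if p_ij <= 0:
        raise PhyloError("endpoint pair has zero transition probability")
    # sample the number of uniformized jumps n:
    # P(n) = Poisson(mu t)(n) * R^n[i,j] / p_ij
    u = rng.random() * p_ij
    log_pois = -mu * t
    Rn = np.eye(model.k)
    cum = 0.0
    n = 0
    while True:
        cum += np.exp(log_pois) * Rn[i, j]
        if cum >= u or n >= max_jumps:
            break
        n += 1
        log_pois += np.log(mu * t) - np.log(n)
        Rn = Rn @ R
    # sample the chain states at the n jumps
    R_pows = [np.eye(model.k)]
    for _ in range(n):
        R_pows.append(R_pows[-1] @ R)
    states = [i]
    for step in range(1, n):
        prev = states[-1]
        w = R[prev, :] * R_pows[n - step][:, j]
        w = np.clip(w, 0, None)
        states.append(int(rng.choice(model.k, p=w / w.sum())))
    if n > 0:
        states.append(j)
    times = np.sort(rng.random(n)) * t
    # collapse virtual jumps into segments
    segments: list[tuple[float, int]] = []
    prev_time = 0.0
    cur_state = i
    for time, state in zip(times, states[1:]):
        if state != cur_state:
            segments.append((time - prev_time, cur_state))
            prev_time = time
            cur_state = state
    segments.append((t - prev_time, cur_state))
    if cur_state != j:  # pragma: no cover - guarded by p_ij > 0
        raise PhyloError("path sampling failed to hit the endpoint")
    return segments


def stochastic_maps(tree: PhyloTree, tip_states: Mapping[str, str],
                    model: MkModel, n_maps: int = 1000,
                    seed: int = 0) -> list[CharacterHistory]:
    """Sample character histories conditional on the tips.

    Node states are drawn root-to-tips from the conditional distributions
    implied by the pruning partials; each branch's path is then sampled
    conditional on its endpoint states by uniformization.
    """
    partials, _ = _down_partials(tree, tip_states, model)
    prior = model.prior()
    nodes = list(tree.preorder())
    P_cache = {}
    for node in nodes:
        if node is not tree.root:
            if node.length is None:
                raise PhyloError(f"missing branch length above {node.label!r}")
            P_cache[id(node)] = model.transition_matrix(node.length)
    rng = np.random.default_rng(seed)
    histories = []
    for _ in range(n_maps):
        node_states: dict = {}
        root_w = prior * partials[id(tree.root)]
        node_states[tree.root] = int(rng.choice(model.k, p=root_w / root_w.sum()))
        for node in nodes:
            if node is tree.root:
                continue
            i = node_states[node.parent]
            w = P_cache[id(node)][i, :] * partials[id(node)]
            node_states[node] = int(rng.choice(model.k, p=w / w.sum()))
        branch_segments = {}
        for node in nodes:
            if node is tree.root:
                continue
            segs = _sample_path(node_states[node.parent], node_states[node],
                                node.length, model, rng)
            branch_segments[node] = [(d, model.states[s]) for d, s in segs]
        history = CharacterHistory(
            tree,
            {n: model.states[s] for n, s in node_states.items()},
            branch_segments,
        )
        histories.append(history)
    return histories


# ---------------------------------------------------------------------------
# Transition censuses and posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class TransitionSummary:
    mean_total: float
    mean_terminal: float
    mean_internal: float
    matrix: pd.DataFrame           # mean per-map counts, rows=from, cols=to
    generalist_fraction: float | None
    n_maps: int


def count_transitions(histories: Sequence[CharacterHistory],
                      generalist_state: str = "generalist",
                      ) -> TransitionSummary:
    """Transition census over sampled maps.

    Counts state changes along branches, split by terminal vs internal
    branches, plus the mean from->to matrix and the pooled fraction of
    transitions with the generalist state as source or target.
    """
    if not histories:
        raise PhyloError("need at least one history")
    states = sorted({s for h in histories
                     for segs in h.branch_segments.values() for _, s in segs})
    mat = np.zeros((len(states), len(states)))
    sidx = {s: i for i, s in enumerate(states)}
    totals, terminals, internals = [], [], []
    n_generalist = 0
    n_all = 0
    for h in histories:
        total = terminal = 0
        for node, segs in h.branch_segments.items():
            changes = len(segs) - 1
            total += changes
            if node.is_leaf:
                terminal += changes
            for (_, s1), (_, s2) in zip(segs, segs[1:]):
                mat[sidx[s1], sidx[s2]] += 1
                n_all += 1
                if generalist_state in (s1, s2):
                    n_generalist += 1
        totals.append(total)
        terminals.append(terminal)
        internals.append(total - terminal)
    n_maps = len(histories)
    frac = n_generalist / n_all if n_all else None
    return TransitionSummary(
        mean_total=float(np.mean(totals)),
        mean_terminal=float(np.mean(terminals)),
        mean_internal=float(np.mean(internals)),
        matrix=pd.DataFrame(mat / n_maps, index=states, columns=states),
        generalist_fraction=frac,
        n_maps=n_maps,
    )


@dataclass
class PosteriorSummary:
    node_posteriors: pd.DataFrame    # rows: node id, columns: states
    summary_states: dict             # node -> argmax state
    transition_branches: list        # child nodes where summary state changes


def summarize_posterior(histories: Sequence[CharacterHistory],
                        tree: PhyloTree) -> PosteriorSummary:
    """Per-node state posteriors across maps and the max-posterior summary.

    Transition branches are those whose parent and child argmax states
    differ (ties broken by state name for determinism).
    """
    if not histories:
        raise PhyloError("need at least one history")
    states = sorted({s for h in histories for s in h.node_states.values()})
    nodes = list(tree.preorder())
    counts = {id(n): np.zeros(len(states)) for n in nodes}
    sidx = {s: i for i, s in enumerate(states)}
    for h in histories:
        for node, state in h.node_states.items():
            counts[id(node)][sidx[state]] += 1
    n_maps = len(histories)
    rows = []
    summary = {}
    for i, node in enumerate(nodes):
        freq = counts[id(node)] / n_maps
        name = node.label if node.is_leaf else f"node{i}"
        rows.append({"node": name, **dict(zip(states, freq))})
        summary[node] = states[int(np.argmax(freq))]
    transition_branches = [
        node for node in nodes
        if node is not tree.root and summary[node.parent] != summary[node]
    ]
    return PosteriorSummary(pd.DataFrame(rows), summary, transition_branches)
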