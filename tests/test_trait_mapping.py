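"""Substrate classification, Mk likelihood, stochastic maps, transitions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from concordscape import synthetic_data
from concordscape.phylo_core import PhyloError, read_tree
from concordscape.trait_mapping import (
    CharacterHistory,
    classify_rearing_table,
    classify_substrate,
    count_transitions,
    fit_mk,
    mk_er,
    mk_loglik,
    MkModel,
    stochastic_maps,
    summarize_posterior,
)


def brute_force_mk(tree, tips, model):
    """Exhaustive ancestral-state sum (oracle for the Mk pruning likelihood)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    prior = model.prior()
    total = 0.0
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assign))
        val = prior[amap[id(tree.root)]]
        for n in nodes:
            if n is tree.root:
                continue
            P = model.transition_matrix(n.length)
            i = amap[id(n.parent)]
            if n.is_leaf:
                state = tips.get(n.label)
                if state is None:
                    continue  # missing tip: marginalized, contributes 1
                val *= P[i, model.state_index(state)]
            else:
                val *= P[i, amap[id(n)]]
        total += val
    return math.log(total)


def brute_force_node_posteriors(tree, tips, model):
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    prior = model.prior()
    marg = {id(n): np.zeros(model.k) for n in internals}
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assign))
        val = prior[amap[id(tree.root)]]
        for n in nodes:
            if n is tree.root:
                continue
            P = model.transition_matrix(n.length)
            i = amap[id(n.parent)]
            j = (model.state_index(tips[n.label]) if n.is_leaf
                 else amap[id(n)])
            val *= P[i, j]
        for n in internals:
            marg[id(n)][amap[id(n)]] += val
    return {id(n): marg[id(n)] / marg[id(n)].sum() for n in internals}


class TestClassifySubstrate:
    @pytest.mark.parametrize("counts,expected", [
        ({"bark": 10}, "bark"),
        ({"bark": 5, "leaf": 5}, "generalist"),
        ({"bark": 7, "leaf": 2, "fungus": 1}, "bark"),
        ({"bark": 3, "leaf": 3, "sap": 3}, "generalist"),
        ({}, "unknown"),
        ({"bark": 0, "leaf": 0}, "unknown"),
    ])
    def test_rule_examples(self, counts, expected):
        assert classify_substrate(counts) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(PhyloError):
            classify_substrate({"bark": -1})

    @settings(max_examples=200, derandomize=True)
    @given(st.dictionaries(
        st.sampled_from(["bark", "leaf", "sap", "fungus", "flower"]),
        st.integers(min_value=0, max_value=50), max_size=5))
    def test_rule_is_total_and_consistent(self, counts):
        call = classify_substrate(counts)
        total = sum(counts.values())
        if total == 0:
            assert call == "unknown"
        elif call not in ("generalist", "unknown"):
            # a specialist's substrate must exceed 2/3, with no second > 1/4
            assert counts[call] / total > 2 / 3
            others = [n / total for c, n in counts.items() if c != call]
            assert all(f <= 0.25 for f in others)
        else:
            fracs = sorted((n / total for n in counts.values()), reverse=True)
            assert sum(f > 0.25 for f in fracs) >= 2 or fracs[0] <= 2 / 3

    def test_rearing_table_classification(self):
        table = pd.DataFrame([
            {"species": "s1", "substrate": "bark", "count": 9},
            {"species": "s1", "substrate": "leaf", "count": 1},
            {"species": "s2", "substrate": "bark", "count": 4},
            {"species": "s2", "substrate": "leaf", "count": 4},
        ])
        calls = classify_rearing_table(table)
        assert dict(zip(calls["species"], calls["call"])) == \
            {"s1": "bark", "s2": "generalist"}


class TestMkLoglik:
    def test_matches_exhaustive_enumeration(self, rng):
        newicks = ["((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);",
                   "(((A:0.3,B:0.7):0.2,C:0.4):0.3,D:1.1);"]
        for k in (2, 3, 4):
            states = [f"s{i}" for i in range(k)]
            rates = rng.uniform(0.1, 0.8, size=(k, k))
            Q = (rates + rates.T) / 2
            np.fill_diagonal(Q, 0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            model = MkModel(tuple(states), Q, "SYM")
            for newick in newicks:
                tree = read_tree(newick)
                tips = {lf: states[rng.integers(k)]
                        for lf in tree.leaf_labels()}
                assert mk_loglik(tree, tips, model) == \
                    pytest.approx(brute_force_mk(tree, tips, model), abs=1e-8)

    def test_vanishing_rate_limit_is_prior_mass(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "x", "C": "x"}
        model = mk_er(["x", "y", "z"], 1e-12)
        assert mk_loglik(tree, tips, model) == \
            pytest.approx(math.log(1 / 3), abs=1e-6)

    def test_missing_tip_on_zero_branch_changes_nothing(self):
        base = read_tree("((A:1,B:1):1,C:2);")
        extended = read_tree("(((A:1,X:0):0,B:1):1,C:2);")
        tips = {"A": "x", "B": "y", "C": "x"}
        model = mk_er(["x", "y"], 0.4)
        assert mk_loglik(extended, tips, model) == \
            pytest.approx(mk_loglik(base, tips, model), abs=1e-10)

    def test_unknown_state_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(PhyloError):
            mk_loglik(tree, {"A": "bogus", "B": "x", "C": "x"},
                      mk_er(["x", "y"], 0.5))


class TestFitMk:
    def test_monomorphic_tips_pin_rate_to_floor(self, balanced_tree_factory):
        tree = balanced_tree_factory(16)
        tips = {f"t{i}": "a" for i in range(16)}
        with pytest.warns(UserWarning, match="fewer than two"):
            fit = fit_mk(tree, tips, states=("a", "b"))
        assert fit.Q[0, 1] < 1e-4

    def test_er_rate_recovery_within_30_percent(self, balanced_tree_factory):
        tree = balanced_tree_factory(200, edge=0.15)
        true = mk_er(["a", "b", "c"], 0.5)
        tips, _ = synthetic_data.simulate_mk_traits(tree, true, seed=8)
        fit = fit_mk(tree, tips, states=("a", "b", "c"))
        assert abs(fit.Q[0, 1] - 0.5) / 0.5 < 0.30

    def test_ard_never_below_er_on_er_data(self, balanced_tree_factory):
        tree = balanced_tree_factory(32, edge=0.3)
        tips, _ = synthetic_data.simulate_mk_traits(
            tree, mk_er(["a", "b"], 0.4), seed=9)
        er = fit_mk(tree, tips, states=("a", "b"), structure="ER")
        ard = fit_mk(tree, tips, states=("a", "b"), structure="ARD")
        assert mk_loglik(tree, tips, ard) >= mk_loglik(tree, tips, er) - 1e-6


class TestStochasticMaps:
    def test_tips_always_match_observations(self):
        tree = read_tree("((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);")
        tips = {"A": "x", "B": "y", "C": "x", "D": "y"}
        model = mk_er(["x", "y"], 0.6)
        for h in stochastic_maps(tree, tips, model, n_maps=50, seed=2):
            for leaf in tree.leaves():
                assert h.node_states[leaf] == tips[leaf.label]

    def test_histories_satisfy_segment_invariants(self):
        tree = read_tree("((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);")
        tips = {"A": "x", "B": "y", "C": "z", "D": "x"}
        model = mk_er(["x", "y", "z"], 0.8)
        for h in stochastic_maps(tree, tips, model, n_maps=100, seed=3):
            h.validate(tol=1e-9)

    def test_near_zero_rate_monomorphic_gives_no_transitions(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "x", "C": "x"}
        model = mk_er(["x", "y"], 1e-9)
        histories = stochastic_maps(tree, tips, model, n_maps=50, seed=4)
        assert all(h.n_transitions() == 0 for h in histories)

    def test_node_posteriors_match_brute_force(self):
        tree = read_tree("((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);")
        tips = {"A": "x", "B": "y", "C": "x", "D": "x"}
        model = mk_er(["x", "y"], 0.4)
        n_maps = 8000
        histories = stochastic_maps(tree, tips, model, n_maps=n_maps, seed=5)
        post = summarize_posterior(histories, tree)
        brute = brute_force_node_posteriors(tree, tips, model)
        internal_rows = post.node_posteriors[
            post.node_posteriors["node"].str.startswith("node")]
        by_node = {n: i for i, n in enumerate(tree.preorder())}
        for _, row in internal_rows.iterrows():
            node = next(n for n, i in by_node.items()
                        if f"node{i}" == row["node"])
            expected = brute[id(node)]
            for s, e in zip(("x", "y"), expected):
                se = math.sqrt(max(e * (1 - e), 1e-9) / n_maps)
                assert abs(row[s] - e) < max(3 * se, 1e-3)

    def test_deterministic_given_seed(self):
        tree = read_tree("((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);")
        tips = {"A": "x", "B": "y", "C": "x", "D": "y"}
        model = mk_er(["x", "y"], 0.6)
        h1 = stochastic_maps(tree, tips, model, n_maps=20, seed=6)
        h2 = stochastic_maps(tree, tips, model, n_maps=20, seed=6)
        for a, b in zip(h1, h2):
            assert a.node_states == b.node_states
            assert a.branch_segments == b.branch_segments


class TestTransitionCensus:
    def test_hand_built_history(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        nodes = {**{n.label: n for n in tree.leaves()}}
        inner = next(n for n in tree.preorder()
                     if not n.is_leaf and n is not tree.root)
        history = CharacterHistory(
            tree,
            {tree.root: "x", inner: "y", nodes["A"]: "y", nodes["B"]: "x",
             nodes["C"]: "x"},
            {
                inner: [(0.4, "x"), (0.6, "y")],          # internal change
                nodes["A"]: [(1.0, "y")],
                nodes["B"]: [(0.3, "y"), (0.7, "x")],     # terminal change
                nodes["C"]: [(1.5, "x"), (0.5, "x2")],    # terminal change
            },
        )
        summary = count_transitions([history])
        assert summary.mean_total == 3
        assert summary.mean_terminal == 2
        assert summary.mean_internal == 1
        assert summary.matrix.loc["x", "y"] == 1
        assert summary.matrix.loc["y", "x"] == 1
        assert summary.matrix.loc["x", "x2"] == 1

    def test_zero_transition_histories(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "x", "C": "x"}
        histories = stochastic_maps(tree, tips, mk_er(["x", "y"], 1e-9),
                                    n_maps=10, seed=7)
        assert count_transitions(histories).mean_total == 0

    def test_posterior_mean_tracks_simulated_truth(self, balanced_tree_factory):
        """Mean posterior transition count is consistent with the truth."""
        tree = balanced_tree_factory(64, edge=0.3)
        true_model = mk_er(["a", "b"], 0.4)
        realized = []
        posterior_means = []
        for seed in range(6):
            tips, truth = synthetic_data.simulate_mk_traits(
                tree, true_model, seed=100 + seed)
            realized.append(truth.n_transitions())
            hx = stochastic_maps(tree, tips, true_model, n_maps=150,
                                 seed=200 + seed)
            posterior_means.append(count_transitions(hx).mean_total)
        realized, posterior_means = np.array(realized), np.array(posterior_means)
        diff = posterior_means - realized
        se = diff.std(ddof=1) / math.sqrt(len(diff))
        # posterior counts sit near the realized truth on average
        assert abs(diff.mean()) < max(3 * se, 0.15 * realized.mean())


class TestPosteriorSummary:
    def test_unanimous_maps_give_degenerate_posteriors(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "x", "C": "x"}
        histories = stochastic_maps(tree, tips, mk_er(["x", "y"], 1e-9),
                                    n_maps=25, seed=8)
        post = summarize_posterior(histories, tree)
        assert (post.node_posteriors["x"] == 1.0).all()
        assert not post.transition_branches

    def test_posteriors_sum_to_one(self):
        tree = read_tree("((A:0.8,B:0.6):0.4,(C:0.5,D:0.9):0.3);")
        tips = {"A": "x", "B": "y", "C": "z", "D": "x"}
        histories = stochastic_maps(tree, tips, mk_er(["x", "y", "z"], 0.7),
                                    n_maps=60, seed=9)
        post = summarize_posterior(histories, tree)
        sums = post.node_posteriors[["x", "y", "z"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
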