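"""Decoding algorithms against the exhaustive-enumeration oracle.

The oracle iterates every assignment of states to nodes and sums/maximizes
directly; the recursive algorithms must reproduce it exactly (up to float
round-off) on random small instances, including multifurcations and
missing observations.
"""

import math

import numpy as np
import pytest

from treehmm import (
    EmissionModel,
    RateParams,
    decode,
    dumb_decode,
    enumerate_oracle,
    read_newick,
    total_loglik,
    updown,
    viterbi,
)
from treehmm.phylo import Node, RootedTree

from conftest import random_instance, random_tree


def assignment_logprob(tree, rates, emissions, scores, assignment):
    """Direct log-probability of one full state assignment (test helper)."""
    pi = rates.equilibrium()
    lp = math.log(pi[assignment[tree.root.index]])
    for node in tree.postorder():
        k = node.index
        if node.is_leaf:
            lp += emissions.log_density(assignment[k], scores[node.name], node.name)
        if node.parent is not None:
            p = rates.transition_probability(
                assignment[node.parent.index], assignment[k], node.length
            )
            lp += math.log(p) if p > 0 else -math.inf
    return lp


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "emission_kind,p_missing",
        [("beta", 0.0), ("beta", 0.25), ("point_mass", 0.0), ("point_mass", 0.3)],
    )
    def test_updown_and_viterbi_match_enumeration(self, emission_kind, p_missing):
        rng = np.random.default_rng(hash((emission_kind, p_missing)) % 2**31)
        checked = 0
        while checked < 25:
            tree, rates, model, scores = random_instance(
                rng, emission_kind=emission_kind, p_missing=p_missing
            )
            oracle = enumerate_oracle(tree, rates, model, scores)
            res = updown(tree, rates, model, scores)
            assert res.log_likelihood == pytest.approx(
                oracle.log_likelihood, rel=1e-10
            )
            assert np.allclose(
                res.node_posterior, oracle.node_marginals, rtol=1e-10, atol=1e-12
            )
            mask = ~np.isnan(oracle.branch_joints)
            assert np.allclose(
                res.branch_joint[mask], oracle.branch_joints[mask],
                rtol=1e-10, atol=1e-12,
            )
            vstates, vlp = viterbi(tree, rates, model, scores)
            assert vlp == pytest.approx(oracle.best_logprob, rel=1e-10)
            # the returned assignment must itself achieve the maximum
            assert assignment_logprob(tree, rates, model, scores, vstates) == (
                pytest.approx(vlp, rel=1e-10)
            )
            checked += 1

    def test_oracle_rejects_large_trees(self, rng):
        tree = random_tree(rng, 12, multifurcate=False)
        with pytest.raises(ValueError, match="oracle"):
            enumerate_oracle(
                tree, RateParams(1, 1), EmissionModel.uniform(),
                {n: 0.5 for n in tree.leaf_names},
            )


class TestClosedForms:
    def test_single_leaf_point_mass(self):
        tree = RootedTree(Node(name="A", length=0.0))
        rates = RateParams(2.0, 1.0)
        ll = total_loglik(tree, rates, EmissionModel.point_mass(), {"A": 1.0})
        assert ll == pytest.approx(math.log(rates.equilibrium()[1]), rel=1e-12)

    def test_all_missing_scores_give_loglik_zero(self, rng):
        tree, rates, model, scores = random_instance(rng, n_leaves=4)
        scores = {k: math.nan for k in scores}
        assert total_loglik(tree, rates, model, scores) == pytest.approx(0.0, abs=1e-12)

    def test_two_leaves_both_state_one(self):
        tree = read_newick("(A:0.3,B:0.4);")
        res = dumb_decode(tree, RateParams(0.2, 0.2), {"A": 1, "B": 1})
        assert np.array_equal(res.viterbi_states, [1, 1, 1])

    def test_two_leaves_opposite_states_symmetric_root(self):
        tree = read_newick("(A:0.3,B:0.3);")
        res = dumb_decode(tree, RateParams(0.5, 0.5), {"A": 0, "B": 1})
        root = res.node_posterior[tree.root.index]
        assert root == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_uninformative_scores_follow_equilibrium(self):
        tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        rates = RateParams(0.01, 2.0)  # state 0 dominates at equilibrium
        scores = {n: 0.5 for n in tree.leaf_names}
        vstates, _ = viterbi(tree, rates, EmissionModel.uniform(), scores)
        assert np.array_equal(vstates, np.zeros(tree.n_nodes, dtype=int))

    def test_all_leaves_zero_reconstructs_all_zero(self):
        tree = read_newick("((A:0.2,B:0.1):0.3,(C:0.2,D:0.4):0.1);")
        res = dumb_decode(tree, RateParams(0.3, 0.3), {n: 0 for n in "ABCD"})
        assert np.array_equal(res.viterbi_states, np.zeros(tree.n_nodes, dtype=int))

    def test_zero_branch_lengths_force_shared_state(self):
        tree = read_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        res = dumb_decode(tree, RateParams(0.7, 0.2), {"A": 1, "B": 1, "C": 1})
        assert np.allclose(res.node_posterior[:, 1], 1.0, atol=1e-12)

    def test_zero_length_branch_has_zero_event_posterior(self):
        tree = read_newick("((A:0.0,B:0.5):0.3,C:0.2);")
        model = EmissionModel.beta_pair(2, 6, 6, 2)
        res = decode(tree, RateParams(0.4, 0.4), model,
                     {"A": 0.9, "B": 0.2, "C": 0.4})
        a = next(n for n in tree.leaves if n.name == "A")
        assert res.event_posterior[a.index] == pytest.approx(0.0, abs=1e-14)


class TestInvariants:
    def test_posterior_and_joint_normalization(self, rng):
        for _ in range(20):
            tree, rates, model, scores = random_instance(rng)
            res = updown(tree, rates, model, scores)
            assert np.allclose(res.node_posterior.sum(axis=1), 1.0, atol=1e-9)
            for node in tree.postorder():
                if not node.is_root:
                    assert res.branch_joint[node.index].sum() == pytest.approx(
                        1.0, abs=1e-9
                    )
                    # marginalizing the joint over child states gives the
                    # parent's posterior
                    assert np.allclose(
                        res.branch_joint[node.index].sum(axis=1),
                        res.node_posterior[node.parent.index],
                        atol=1e-9,
                    )
            assert res.viterbi_logprob <= res.log_likelihood + 1e-12

    def test_likelihood_invariant_under_child_order(self, rng):
        tree, rates, model, scores = random_instance(rng, n_leaves=5)
        ll = total_loglik(tree, rates, model, scores)
        for node in tree.postorder():
            node.children.reverse()
        permuted = RootedTree(tree.root)
        assert total_loglik(permuted, rates, model, scores) == pytest.approx(
            ll, rel=1e-12
        )

    def test_point_mass_leaf_posteriors_are_certain(self, rng):
        tree, rates, model, scores = random_instance(rng, emission_kind="point_mass")
        res = updown(tree, rates, model, scores)
        for leaf in tree.leaves:
            s = scores[leaf.name]
            if not math.isnan(s):
                assert res.node_posterior[leaf.index, int(s)] == pytest.approx(1.0)

    def test_score_monotonicity_of_leaf_posterior(self):
        # state-1 density stochastically dominates state-0: a larger score
        # can only raise that leaf's state-1 posterior
        tree = read_newick("((A:0.2,B:0.3):0.1,C:0.4);")
        rates = RateParams(0.5, 0.5)
        model = EmissionModel.beta_pair(2, 6, 6, 2)
        a = next(n for n in tree.leaves if n.name == "A")
        last = -1.0
        for s in np.linspace(0.05, 0.95, 10):
            res = updown(tree, rates, model, {"A": s, "B": 0.4, "C": 0.6})
            p1 = res.node_posterior[a.index, 1]
            assert p1 >= last - 1e-12
            last = p1

    def test_root_prior_override(self):
        tree = RootedTree(Node(name="A", length=0.0))
        rates = RateParams(2.0, 1.0)
        model = EmissionModel.uniform()
        # flat prior instead of equilibrium: total probability is unchanged
        # for uninformative emissions, and a certain prior pins the root
        assert total_loglik(tree, rates, model, {"A": 0.5},
                            root_prior=(0.5, 0.5)) == pytest.approx(0.0, abs=1e-12)
        res = updown(tree, rates, model, {"A": 0.5}, root_prior=(1.0, 0.0))
        assert res.node_posterior[tree.root.index, 0] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="root prior"):
            total_loglik(tree, rates, model, {"A": 0.5}, root_prior=(0.9, 0.3))

    def test_missing_leaf_score_required_explicitly(self):
        tree = read_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError, match="no entry"):
            total_loglik(tree, RateParams(1, 1), EmissionModel.uniform(), {"A": 0.5})


class TestDumbMode:
    def test_identical_to_point_mass_decode(self, rng):
        tree, rates, _, _ = random_instance(rng, n_leaves=5)
        states = {n: int(rng.integers(2)) for n in tree.leaf_names}
        via_dumb = dumb_decode(tree, rates, states)
        via_point = decode(
            tree, rates, EmissionModel.point_mass(),
            {k: float(v) for k, v in states.items()},
        )
        # same code path: results are bitwise identical
        assert via_dumb.log_likelihood == via_point.log_likelihood
        assert np.array_equal(via_dumb.node_posterior, via_point.node_posterior)
        assert np.array_equal(
            via_dumb.branch_joint, via_point.branch_joint, equal_nan=True
        )
        assert np.array_equal(via_dumb.viterbi_states, via_point.viterbi_states)

    def test_matches_discrete_likelihood_by_enumeration(self, rng):
        # with observed leaf states the model reduces to the classical
        # discrete-trait likelihood: a sum over internal assignments only
        tree, rates, _, _ = random_instance(rng, n_leaves=4)
        states = {n: int(rng.integers(2)) for n in tree.leaf_names}
        pi = rates.equilibrium()
        total = 0.0
        internal = [n for n in tree.postorder() if not n.is_leaf]
        import itertools

        for combo in itertools.product((0, 1), repeat=len(internal)):
            assign = {}
            for node, s in zip(internal, combo):
                assign[node.index] = s
            for leaf in tree.leaves:
                assign[leaf.index] = states[leaf.name]
            p = pi[assign[tree.root.index]]
            for node in tree.postorder():
                if node.parent is not None:
                    p *= rates.transition_probability(
                        assign[node.parent.index], assign[node.index], node.length
                    )
            total += p
        res = dumb_decode(tree, rates, states)
        assert res.log_likelihood == pytest.approx(math.log(total), rel=1e-10)

    def test_invalid_state_rejected(self):
        tree = read_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError, match="state must be"):
            dumb_decode(tree, RateParams(1, 1), {"A": 2, "B": 0})

    def test_missing_state_marginalized(self, rng):
        tree = read_newick("((A:0.2,B:0.3):0.1,C:0.4);")
        rates = RateParams(0.8, 0.4)
        res = dumb_decode(tree, rates, {"A": 1, "B": None, "C": 0})
        # oracle with B marginalized
        oracle = enumerate_oracle(
            tree, rates, EmissionModel.point_mass(),
            {"A": 1.0, "B": math.nan, "C": 0.0},
        )
        assert np.allclose(res.node_posterior, oracle.node_marginals, rtol=1e-10)


class TestResultTables:
    def test_frames_shape_and_columns(self, rng):
        tree, rates, model, scores = random_instance(rng, n_leaves=4)
        res = decode(tree, rates, model, scores)
        nodes = res.nodes_frame()
        branches = res.branches_frame()
        assert len(nodes) == tree.n_nodes
        assert len(branches) == tree.n_nodes - 1
        assert {"P_state0", "P_state1", "posterior_state", "viterbi_state"} <= set(
            nodes.columns
        )
        assert {"P_gain", "P_loss", "P_event"} <= set(branches.columns)
        assert res.expected_event_count() == pytest.approx(
            branches["P_event"].sum(), rel=1e-12
        )
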