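"""Decoding algorithms for the tree HMM.

Hidden binary states live at every node of a rooted tree and evolve along
branches under a two-state continuous-time Markov chain; leaves emit
continuous scores through per-state densities. Three questions are answered
here:

* the total probability of the observed scores (Felsenstein-style pruning,
  summing over all hidden state assignments),
* the jointly most probable assignment of states to all nodes — including
  the leaves, whose observed scores do not pin their states down — via a
  tree Viterbi recursion with traceback,
* per-node state posteriors and per-branch change ("event") posteriors via
  the up-down algorithm, the tree analogue of forward-backward: *down*
  variables are subtree likelihoods computed leaf-to-root, *up* variables
  are rest-of-tree likelihoods computed root-to-leaf, and their product over
  the total probability gives the posterior.

All recursions are written over an arbitrary child list, so multifurcating
trees work; state arithmetic is scalar (two states) with per-node rescaling
against underflow. An exhaustive-enumeration oracle over all 2^n
assignments backs every algorithm in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .emissions import EmissionModel
from .phylo import Node, RateParams, RootedTree

__all__ = [
    "DecodingResult",
    "decode",
    "dumb_decode",
    "total_loglik",
    "viterbi",
    "updown",
    "enumerate_oracle",
]

_NEG_INF = float("-inf")


@dataclass
class DecodingResult:
    """Everything a decoding run produces, indexed by node postorder index.

    ``branch_joint[k, i, j]`` is the posterior probability that node k's
    parent is in state i and node k in state j; the root row is NaN. Event
    posteriors follow: gain = joint(0,1), loss = joint(1,0).
    """

    tree: RootedTree
    log_likelihood: float
    node_posterior: np.ndarray  # (n_nodes, 2)
    posterior_states: np.ndarray  # (n_nodes,) argmax of the posterior
    viterbi_states: np.ndarray  # (n_nodes,)
    viterbi_logprob: float
    branch_joint: np.ndarray  # (n_nodes, 2, 2); NaN at the root row

    @property
    def gain_posterior(self) -> np.ndarray:
        return self.branch_joint[:, 0, 1]

    @property
    def loss_posterior(self) -> np.ndarray:
        return self.branch_joint[:, 1, 0]

    @property
    def event_posterior(self) -> np.ndarray:
        return self.gain_posterior + self.loss_posterior

    def expected_event_count(self) -> float:
        ev = self.event_posterior
        return float(np.nansum(ev))

    def called_events(self, cutoff: float = 0.5) -> np.ndarray:
        """Binary per-branch event calls at a posterior cutoff (root: False)."""
        ev = self.event_posterior
        return np.where(np.isnan(ev), False, ev > cutoff)

    def nodes_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.index,
                "node_name": n.name or "",
                "is_leaf": n.is_leaf,
                "P_state0": self.node_posterior[n.index, 0],
                "P_state1": self.node_posterior[n.index, 1],
                "posterior_state": int(self.posterior_states[n.index]),
                "viterbi_state": int(self.viterbi_states[n.index]),
            }
            for n in self.tree.postorder()
        ]
        return pd.DataFrame(rows)

    def branches_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent_id": n.parent.index,
                "child_id": n.index,
                "child_name": n.name or "",
                "branch_length": n.length,
                "P_gain": self.branch_joint[n.index, 0, 1],
                "P_loss": self.branch_joint[n.index, 1, 0],
                "P_event": self.branch_joint[n.index, 0, 1]
                + self.branch_joint[n.index, 1, 0],
            }
            for n in self.tree.postorder()
            if not n.is_root
        ]
        return pd.DataFrame(rows)


# -- shared plumbing --------------------------------------------------------


def _leaf_observation(scores: Mapping[str, float], node: Node) -> float:
    try:
        return scores[node.name]
    except KeyError:
        raise ValueError(
            f"leaf {node.name!r} has no entry in the score table; add it or "
            "mark it missing (NaN)"
        ) from None


def _log_emissions(
    tree: RootedTree, emissions: EmissionModel, scores: Mapping[str, float]
) -> list[tuple[float, float]]:
    """Per-node (log e(0), log e(1)); internal nodes and missing leaves emit 1."""
    out = []
    for node in tree.postorder():
        if node.is_leaf:
            s = _leaf_observation(scores, node)
            out.append(
                (
                    emissions.log_density(0, s, node.name),
                    emissions.log_density(1, s, node.name),
                )
            )
        else:
            out.append((0.0, 0.0))
    return out


def _transition_rows(rates: RateParams, t: float):
    """((P00, P01), (P10, P11)) over a branch of length t."""
    pi0, pi1 = rates.equilibrium()
    decay = math.exp(-(rates.lambda01 + rates.lambda10) * t)
    p00 = pi0 + pi1 * decay
    p11 = pi1 + pi0 * decay
    return ((p00, 1.0 - p00), (1.0 - p11, p11))


def _resolve_root_prior(rates, root_prior):
    if root_prior is None:
        return rates.equilibrium()
    p0, p1 = float(root_prior[0]), float(root_prior[1])
    if p0 < 0 or p1 < 0 or abs(p0 + p1 - 1.0) > 1e-9:
        raise ValueError("root prior must be a probability pair summing to 1")
    return p0, p1


def _down_pass(tree, rates, elog, root_prior=None):
    """Scaled subtree likelihoods.

    Returns (down, logscale, loglik): ``down[k][j]`` is proportional to
    P(scores below k | state j at k) including k's own emission, normalized
    so max_j down[k][j] == 1 with the log of the true magnitude accumulated
    in ``logscale[k]``.
    """
    n = tree.n_nodes
    down = [None] * n
    logscale = [0.0] * n
    acc0 = [1.0] * n
    acc1 = [1.0] * n
    for node in tree.postorder():
        k = node.index
        e0, e1 = elog[k]
        d0 = (math.exp(e0) if e0 > _NEG_INF else 0.0) * acc0[k]
        d1 = (math.exp(e1) if e1 > _NEG_INF else 0.0) * acc1[k]
        s = d0 if d0 >= d1 else d1
        if s > 0.0:
            d0 /= s
            d1 /= s
            logscale[k] += math.log(s)
        else:
            logscale[k] = _NEG_INF
        down[k] = (d0, d1)
        if node.parent is not None:
            p = node.parent.index
            (p00, p01), (p10, p11) = _transition_rows(rates, node.length)
            acc0[p] *= p00 * d0 + p01 * d1
            acc1[p] *= p10 * d0 + p11 * d1
            logscale[p] += logscale[k]
    r = tree.root.index
    pi0, pi1 = _resolve_root_prior(rates, root_prior)
    total = pi0 * down[r][0] + pi1 * down[r][1]
    loglik = math.log(total) + logscale[r] if total > 0 else _NEG_INF
    return down, logscale, loglik


def total_loglik(
    tree: RootedTree,
    rates: RateParams,
    emissions: EmissionModel,
    scores: Mapping[str, float],
    root_prior: tuple[float, float] | None = None,
) -> float:
    """Log of the total observation probability, summed over all hidden
    state assignments (root weighted by the equilibrium prior unless
    ``root_prior`` overrides it)."""
    elog = _log_emissions(tree, emissions, scores)
    return _down_pass(tree, rates, elog, root_prior)[2]


# -- Viterbi ----------------------------------------------------------------


def viterbi(
    tree: RootedTree,
    rates: RateParams,
    emissions: EmissionModel,
    scores: Mapping[str, float],
    root_prior: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Jointly most probable state assignment for every node.

    Upward max-product over children, traceback from the root argmax. Ties
    are broken toward state 0 at every maximization, deterministically.
    Returns (states indexed by node postorder index, log-probability of the
    best assignment).
    """
    elog = _log_emissions(tree, emissions, scores)
    n = tree.n_nodes
    V = [None] * n
    # back[k][j] = best state of child k given its parent is in state j
    back = [None] * n
    for node in tree.postorder():
        k = node.index
        v0, v1 = elog[k]
        for child in node.children:
            c = child.index
            rows = _transition_rows(rates, child.length)
            best = [0.0, 0.0]
            choice = [0, 0]
            for j in (0, 1):
                cand0 = _log(rows[j][0]) + V[c][0]
                cand1 = _log(rows[j][1]) + V[c][1]
                if cand1 > cand0:
                    best[j], choice[j] = cand1, 1
                else:
                    best[j], choice[j] = cand0, 0
            back[c] = tuple(choice)
            v0 += best[0]
            v1 += best[1]
        V[k] = (v0, v1)

    pi0, pi1 = _resolve_root_prior(rates, root_prior)
    r = tree.root.index
    root0 = _log(pi0) + V[r][0]
    root1 = _log(pi1) + V[r][1]
    states = np.zeros(n, dtype=np.int64)
    states[r] = 1 if root1 > root0 else 0
    logprob = max(root0, root1)
    for node in tree.preorder():
        if node.is_root:
            continue
        states[node.index] = back[node.index][states[node.parent.index]]
    return states, float(logprob)


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else _NEG_INF


# -- up-down posterior decoding ---------------------------------------------


def updown(
    tree: RootedTree,
    rates: RateParams,
    emissions: EmissionModel,
    scores: Mapping[str, float],
    root_prior: tuple[float, float] | None = None,
) -> DecodingResult:
    """Posterior decoding plus Viterbi, packaged as a DecodingResult.

    For every node k and state j the posterior is up_k(j)·down_k(j)/P(D);
    the per-branch joint over (parent state, child state) combines the
    parent's up variable, its other children's down messages, the branch
    transition and the child's down variable, normalized by P(D).
    """
    elog = _log_emissions(tree, emissions, scores)
    down, dscale, loglik = _down_pass(tree, rates, elog, root_prior)
    if loglik == _NEG_INF:
        raise ValueError("observations have probability 0 under the model")
    n = tree.n_nodes
    pi0, pi1 = _resolve_root_prior(rates, root_prior)

    # child messages S_c(i) = sum_m P_im(t_c) down_c(m) (normalized scale)
    msg = [None] * n
    for node in tree.postorder():
        if node.is_root:
            continue
        c = node.index
        (p00, p01), (p10, p11) = _transition_rows(rates, node.length)
        d0, d1 = down[c]
        msg[c] = (p00 * d0 + p01 * d1, p10 * d0 + p11 * d1)

    up = [None] * n
    upscale = [0.0] * n
    up[tree.root.index] = (pi0, pi1)
    posterior = np.zeros((n, 2))
    joint = np.full((n, 2, 2), np.nan)

    for node in tree.preorder():
        k = node.index
        # node posterior from up × down (log-scaled)
        log_terms = []
        for j in (0, 1):
            val = up[k][j] * down[k][j]
            log_terms.append(
                _log(val) + upscale[k] + dscale[k] if val > 0 else _NEG_INF
            )
        m = max(log_terms)
        if m == _NEG_INF:
            raise ValueError("zero posterior mass at a node; inconsistent input")
        w = [math.exp(t - m) for t in log_terms]
        z = w[0] + w[1]
        posterior[k, 0] = w[0] / z
        posterior[k, 1] = w[1] / z

        if not node.children:
            continue
        e0, e1 = elog[k]
        pe = (math.exp(e0) if e0 > _NEG_INF else 0.0,
              math.exp(e1) if e1 > _NEG_INF else 0.0)
        children = node.children
        for child in children:
            c = child.index
            # leave-one-out product of sibling messages, per parent state
            sib0 = sib1 = 1.0
            sib_scale = 0.0
            for other in children:
                if other is child:
                    continue
                o = other.index
                sib0 *= msg[o][0]
                sib1 *= msg[o][1]
                sib_scale += dscale[o]
            rows = _transition_rows(rates, child.length)
            base0 = up[k][0] * pe[0] * sib0
            base1 = up[k][1] * pe[1] * sib1
            u0 = rows[0][0] * base0 + rows[1][0] * base1
            u1 = rows[0][1] * base0 + rows[1][1] * base1
            s = u0 if u0 >= u1 else u1
            sc = upscale[k] + sib_scale
            if s > 0.0:
                u0 /= s
                u1 /= s
                sc += math.log(s)
            up[c] = (u0, u1)
            upscale[c] = sc
            # branch joint: parent state i, child state j
            logz = loglik
            for i, basei in ((0, base0), (1, base1)):
                for j in (0, 1):
                    val = basei * rows[i][j] * down[c][j]
                    lg = (
                        _log(val) + upscale[k] + sib_scale + dscale[c]
                        if val > 0
                        else _NEG_INF
                    )
                    joint[c, i, j] = math.exp(lg - logz) if lg > _NEG_INF else 0.0
            joint[c] /= joint[c].sum()  # absorb float round-off

    vstates, vlogprob = viterbi(tree, rates, emissions, scores, root_prior)
    return DecodingResult(
        tree=tree,
        log_likelihood=loglik,
        node_posterior=posterior,
        posterior_states=(posterior[:, 1] > posterior[:, 0]).astype(np.int64),
        viterbi_states=vstates,
        viterbi_logprob=vlogprob,
        branch_joint=joint,
    )


def decode(
    tree: RootedTree,
    rates: RateParams,
    emissions: EmissionModel,
    scores: Mapping[str, float],
    root_prior: tuple[float, float] | None = None,
) -> DecodingResult:
    """Full decoding (posteriors, events, Viterbi) — alias of :func:`updown`."""
    return updown(tree, rates, emissions, scores, root_prior)


def dumb_decode(
    tree: RootedTree,
    rates: RateParams,
    leaf_states: Mapping[str, int | None],
) -> DecodingResult:
    """Decoding from directly observed discrete 0/1 leaf states (dumb mode).

    This is exactly :func:`decode` with point-mass emissions — the classical
    discrete ancestral reconstruction setting — and shares all code paths.
    Missing states (None/NaN) are marginalized.
    """
    scores: dict[str, float] = {}
    for leaf, s in leaf_states.items():
        if s is None or (isinstance(s, float) and math.isnan(s)):
            scores[leaf] = math.nan
        elif s in (0, 1):
            scores[leaf] = float(s)
        else:
            raise ValueError(f"leaf {leaf!r}: state must be 0, 1 or missing, got {s!r}")
    return decode(tree, rates, EmissionModel.point_mass(), scores)


# -- exhaustive enumeration oracle ------------------------------------------


@dataclass
class EnumerationResult:
    total_probability: float
    log_likelihood: float
    node_marginals: np.ndarray  # (n_nodes, 2)
    branch_joints: np.ndarray  # (n_nodes, 2, 2); NaN at root
    best_assignment: np.ndarray  # (n_nodes,)
    best_logprob: float


def enumerate_oracle(
    tree: RootedTree,
    rates: RateParams,
    emissions: EmissionModel,
    scores: Mapping[str, float],
    max_nodes: int = 16,
) -> EnumerationResult:
    """Exact decoding by brute force over all 2^n state assignments.

    Exponential: refuses trees above ``max_nodes`` nodes. Exists to verify
    the recursive algorithms on small instances.
    """
    n = tree.n_nodes
    if n > max_nodes:
        raise ValueError(f"tree has {n} nodes; oracle limited to {max_nodes}")
    elog = _log_emissions(tree, emissions, scores)
    pi = rates.equilibrium()

    total = 0.0
    marg = np.zeros((n, 2))
    joints = np.zeros((n, 2, 2))
    best_lp = _NEG_INF
    best = None
    for assign in itertools.product((0, 1), repeat=n):
        lp = _log(pi[assign[tree.root.index]])
        for node in tree.postorder():
            k = node.index
            lp += elog[k][assign[k]]
            if node.parent is not None:
                lp += _log(
                    rates.transition_probability(
                        assign[node.parent.index], assign[k], node.length
                    )
                )
            if lp == _NEG_INF:
                break
        if lp == _NEG_INF:
            continue
        p = math.exp(lp)
        total += p
        for node in tree.postorder():
            k = node.index
            marg[k, assign[k]] += p
            if node.parent is not None:
                joints[k, assign[node.parent.index], assign[k]] += p
        if lp > best_lp:
            best_lp = lp
            best = assign

    if total <= 0:
        raise ValueError("observations have probability 0 under the model")
    marg /= total
    joints /= total
    for node in tree.postorder():
        if node.is_root:
            joints[node.index] = np.nan
    return EnumerationResult(
        total_probability=total,
        log_likelihood=math.log(total),
        node_marginals=marg,
        branch_joints=joints,
        best_assignment=np.array(best, dtype=np.int64),
        best_logprob=best_lp,
    )
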