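"""Flattened-array pruning likelihood for repeated evaluation.

ML optimization and MCMC evaluate the same dataset likelihood thousands of
times with only the two transition rates changing. This module flattens a
dataset of trees into postorder-ordered arrays (parent index, branch
length, per-node linear emissions) once, then evaluates the summed
log-likelihood with a numba-compiled kernel. Falls back to pure Python if
numba is unavailable. Agreement with decode.total_loglik is asserted in the
test suite.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .decode import _log_emissions
from .emissions import EmissionModel
from .phylo import RateParams, RootedTree

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _loglik_kernel(parent, t, e0, e1, pi0, pi1, lam_total):  # pragma: no cover
    n = parent.shape[0]
    acc0 = np.ones(n)
    acc1 = np.ones(n)
    lsc = np.zeros(n)
    total = 0.0
    for k in range(n):
        d0 = e0[k] * acc0[k]
        d1 = e1[k] * acc1[k]
        s = d0 if d0 >= d1 else d1
        if s <= 0.0:
            return -np.inf
        d0 /= s
        d1 /= s
        ls = lsc[k] + np.log(s)
        p = parent[k]
        if p < 0:
            root = pi0 * d0 + pi1 * d1
            if root <= 0.0:
                return -np.inf
            total += np.log(root) + ls
        else:
            decay = np.exp(-lam_total * t[k])
            p00 = pi0 + pi1 * decay
            p11 = pi1 + pi0 * decay
            acc0[p] *= p00 * d0 + (1.0 - p00) * d1
            acc1[p] *= (1.0 - p11) * d0 + p11 * d1
            lsc[p] += ls
    return total


class FlatDataset:
    """Postorder-flattened trees + fixed emissions for fast rate likelihoods."""

    def __init__(
        self,
        dataset: Sequence[tuple[RootedTree, Mapping[str, float]]],
        emissions: EmissionModel,
    ):
        parents: list[int] = []
        lengths: list[float] = []
        e0: list[float] = []
        e1: list[float] = []
        offset = 0
        for tree, scores in dataset:
            elog = _log_emissions(tree, emissions, scores)
            for node in tree.postorder():
                k = node.index
                parents.append(-1 if node.is_root else offset + node.parent.index)
                lengths.append(node.length)
                le0, le1 = elog[k]
                e0.append(math.exp(le0) if le0 > -math.inf else 0.0)
                e1.append(math.exp(le1) if le1 > -math.inf else 0.0)
            offset += tree.n_nodes
        self.parent = np.asarray(parents, dtype=np.int64)
        self.t = np.asarray(lengths, dtype=np.float64)
        self.e0 = np.asarray(e0, dtype=np.float64)
        self.e1 = np.asarray(e1, dtype=np.float64)
        self.n_trees = len(dataset)

    def loglik(self, lambda01: float, lambda10: float) -> float:
        """Summed log-likelihood of the dataset at the given rates."""
        if not (lambda01 > 0 and lambda10 > 0):
            return -math.inf
        total = lambda01 + lambda10
        pi0 = lambda10 / total
        pi1 = lambda01 / total
        return float(
            _loglik_kernel(self.parent, self.t, self.e0, self.e1, pi0, pi1, total)
        )

    def loglik_rates(self, rates: RateParams) -> float:
        return self.loglik(rates.lambda01, rates.lambda10)
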