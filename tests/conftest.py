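"""Shared fixtures and the random-instance generator for oracle tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from treehmm import EmissionModel, RateParams, RootedTree
from treehmm.phylo import Node


def random_tree(rng: np.random.Generator, n_leaves: int, multifurcate: bool = True,
                max_length: float = 1.0) -> RootedTree:
    """Random topology by joining random groups, branch lengths U[0, max]."""
    nodes = [
        Node(name=f"L{i}", length=float(rng.uniform(0, max_length)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        k = 3 if (multifurcate and len(nodes) >= 3 and rng.random() < 0.2) else 2
        parent = Node(length=float(rng.uniform(0, max_length)))
        for _ in range(k):
            parent.add_child(nodes.pop(int(rng.integers(len(nodes)))))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return RootedTree(root)


def random_instance(
    rng: np.random.Generator,
    n_leaves: int | None = None,
    emission_kind: str = "beta",
    p_missing: float = 0.0,
    multifurcate: bool = True,
):
    """A random decoding problem small enough for exhaustive enumeration.

    Leaf count 2–6, branch lengths in [0, 1], rates in [0.05, 5]; emissions
    either a random beta pair or point masses on discrete observations.
    """
    if n_leaves is None:
        n_leaves = int(rng.integers(2, 7))
    tree = random_tree(rng, n_leaves, multifurcate=multifurcate)
    rates = RateParams(float(rng.uniform(0.05, 5)), float(rng.uniform(0.05, 5)))
    scores: dict[str, float] = {}
    if emission_kind == "beta":
        model = EmissionModel.beta_pair(
            *(float(rng.uniform(0.5, 8.0)) for _ in range(4))
        )
        for name in tree.leaf_names:
            scores[name] = (
                math.nan if rng.random() < p_missing else float(rng.beta(2, 2))
            )
    elif emission_kind == "point_mass":
        model = EmissionModel.point_mass()
        for name in tree.leaf_names:
            scores[name] = (
                math.nan if rng.random() < p_missing else float(rng.integers(2))
            )
    else:
        raise ValueError(emission_kind)
    return tree, rates, model, scores


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
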