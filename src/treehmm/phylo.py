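"""Rooted trees with branch lengths and the two-state evolutionary kernel.

The tree container is deliberately small: decoding visits every node a
handful of times per likelihood evaluation, so nodes are plain objects with
integer indices into flat arrays, and traversal orders are computed once.
Newick reading/writing is delegated to dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "RootedTree",
    "RateParams",
    "NewickError",
    "read_newick",
    "write_newick",
]


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


class Node:
    """A tree node: ``index`` is its position in postorder."""

    __slots__ = ("index", "name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.index: int = -1
        self.name = name
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.index} {self.name!r} ({kind}, t={self.length:g})>"


class RootedTree:
    """Rooted tree with non-negative branch lengths and uniquely named leaves.

    Nodes are indexed in postorder (children before parents, root last),
    which is the evaluation order of every upward recursion; preorder is its
    reverse restriction used by downward passes.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = list(_postorder(root))
        for i, node in enumerate(self.nodes):
            node.index = i
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def postorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def preorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.nodes if not n.is_root)

    def _validate(self) -> None:
        seen_names: set[str] = set()
        for node in self.nodes:
            if not math.isfinite(node.length) or node.length < 0:
                raise ValueError(
                    f"branch length of node {node.name!r} is {node.length!r}; "
                    "must be finite and >= 0"
                )
            if node.is_leaf:
                if not node.name:
                    raise ValueError("every leaf must be named")
                if node.name in seen_names:
                    raise ValueError(f"duplicate leaf name {node.name!r}")
                seen_names.add(node.name)
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("inconsistent parent link")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree {len(self.leaves)} leaves, {self.n_nodes} nodes>"


def _postorder(root: Node) -> Iterator[Node]:
    # iterative to keep deep trees off the Python call stack
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


# -- Newick I/O -------------------------------------------------------------


def read_newick(text: str, default_branch_length: float | None = None) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Multifurcations are kept as-is; an unrooted trifurcation at the top level
    therefore becomes a multifurcating root. A missing branch length is an
    error unless ``default_branch_length`` supplies a substitute — silently
    assuming zero would change the inference.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickError(f"could not parse Newick input: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is None:
                length = 0.0  # root edge carries no information
            elif default_branch_length is not None:
                length = default_branch_length
            else:
                raise NewickError(
                    f"node {label!r} has no branch length; supply one "
                    "explicitly or pass default_branch_length"
                )
        node = Node(name=label, length=length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    try:
        return RootedTree(convert(dtree.seed_node))
    except ValueError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(
    tree: RootedTree, node_comment: Callable[[Node], str] | None = None
) -> str:
    """Serialize to Newick; ``node_comment`` may attach ``[...]`` annotations."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            core = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            core = f"({inner})" + (node.name or "")
        if node_comment is not None:
            core += f"[{node_comment(node)}]"
        if node.is_root:
            return core
        return f"{core}:{node.length:.10g}"

    return fmt(tree.root) + ";"


# -- two-state continuous-time Markov kernel --------------------------------


@dataclass(frozen=True)
class RateParams:
    """Gain/loss rates of the two-state continuous-time Markov chain.

    ``lambda01`` is the 0→1 (gain) rate and ``lambda10`` the 1→0 (loss)
    rate, both per unit of branch length in the tree's own time units. The
    transition probability over a branch of length ``t`` is

        P_ij(t) = pi_j + (delta_ij - pi_j) * exp(-(lambda01 + lambda10) t)

    with stationary distribution pi = (lambda10, lambda01) / (lambda01 +
    lambda10), which also serves as the default root prior.
    """

    lambda01: float
    lambda10: float

    def __post_init__(self) -> None:
        for name in ("lambda01", "lambda10"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    def equilibrium(self) -> tuple[float, float]:
        total = self.lambda01 + self.lambda10
        return self.lambda10 / total, self.lambda01 / total

    def transition_probability(self, i: int, j: int, t: float) -> float:
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        if i not in (0, 1) or j not in (0, 1):
            raise ValueError("states must be 0 or 1")
        pi = self.equilibrium()
        decay = math.exp(-(self.lambda01 + self.lambda10) * t)
        return pi[j] + ((1.0 if i == j else 0.0) - pi[j]) * decay

    def transition_matrix(self, t: float) -> np.ndarray:
        """The 2×2 matrix P(t), rows = parent state, columns = child state."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        pi0, pi1 = self.equilibrium()
        decay = math.exp(-(self.lambda01 + self.lambda10) * t)
        return np.array(
            [
                [pi0 + pi1 * decay, pi1 - pi1 * decay],
                [pi0 - pi0 * decay, pi1 + pi0 * decay],
            ]
        )


def tree_from_parent_lists(
    names: Sequence[str | None],
    parents: Sequence[int],
    lengths: Sequence[float],
) -> RootedTree:
    """Build a tree from parallel arrays (parent index -1 marks the root).

    Children keep the order in which they appear in the arrays. Mostly a
    convenience for simulation and tests.
    """
    nodes = [Node(name=n, length=t) for n, t in zip(names, lengths)]
    root = None
    for node, p in zip(nodes, parents):
        if p < 0:
            if root is not None:
                raise ValueError("multiple roots")
            root = node
        else:
            nodes[p].add_child(node)
    if root is None:
        raise ValueError("no root (parent -1) found")
    return RootedTree(root)
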