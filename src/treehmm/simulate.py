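"""Simulation study generator and benchmark harness.

Random binary trees are grown by repeated bifurcation: each new branch
draws its length from a configurable distribution, and a lineage becomes a
leaf once its distance from the root exceeds a depth cutoff (default 0.5).
States evolve down the tree under the two-state chain; leaf scores are then
drawn from the per-state beta densities. The confusability of the two
densities is controlled by their overlap coefficient ∫ min(f0, f1), using a
mirrored Beta(a, b) / Beta(b, a) pair with fixed shape sum.

The benchmark decodes each tree three ways — from the raw scores with the
true densities ("thmm"), from threshold-discretized states ("dumb"), and
from the true leaf states ("known") — and aggregates state accuracy,
normalized event counts and the Matthews correlation of branch-level event
calls against the simulated truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate, optimize
from sklearn.metrics import matthews_corrcoef

from .decode import DecodingResult, decode, dumb_decode
from .emissions import BetaDensity, EmissionModel, derive_threshold, discretize
from .phylo import Node, RateParams, RootedTree

__all__ = [
    "SimulationConfig",
    "SimulatedTree",
    "BenchmarkReport",
    "MethodReport",
    "sample_tree",
    "simulate_dataset",
    "emit_scores",
    "overlap_coefficient",
    "betas_from_overlap",
    "benchmark",
    "grey_zone_counts",
    "prior_leaf_probabilities",
]

METHODS = ("thmm", "dumb", "known")


def lognormal_branch_sampler(
    mu: float = -2.5, sigma: float = 1.0, cutoff: float = 0.5
) -> Callable[[np.random.Generator], float]:
    """Log-normal branch lengths truncated to (0, cutoff] by rejection.

    A stand-in for an empirical branch-length sample: the defaults give
    trees in the tens-of-leaves range under the default depth cutoff.
    """

    def draw(rng: np.random.Generator) -> float:
        for _ in range(1000):
            t = float(rng.lognormal(mu, sigma))
            if 0.0 < t <= cutoff:
                return t
        raise RuntimeError("branch-length sampler kept exceeding the cutoff")

    return draw


def empirical_branch_sampler(
    sample: Sequence[float],
) -> Callable[[np.random.Generator], float]:
    """Resample branch lengths from an observed collection."""
    arr = np.asarray(sample, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("branch-length sample must be strictly positive")

    def draw(rng: np.random.Generator) -> float:
        return float(arr[rng.integers(len(arr))])

    return draw


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults are the anchor setting of the simulation study: symmetric
    transition rate 0.2, score-density overlap 0.19, depth cutoff 0.5, 400
    trees. ``beta_params`` (a0, b0, a1, b1) overrides the overlap-derived
    mirrored pair when given.
    """

    lambda01: float = 0.2
    lambda10: float = 0.2
    overlap: float = 0.19
    beta_params: tuple[float, float, float, float] | None = None
    shape_sum: float = 10.0
    depth_cutoff: float = 0.5
    n_trees: int = 400
    branch_sampler: Callable[[np.random.Generator], float] | None = None
    seed: int | None = None
    max_nodes_per_tree: int = 100_000

    def __post_init__(self):
        if self.depth_cutoff <= 0:
            raise ValueError("depth_cutoff must be > 0")
        if not 0.0 < self.overlap < 1.0:
            raise ValueError("overlap must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @property
    def rates(self) -> RateParams:
        return RateParams(self.lambda01, self.lambda10)

    def emission_model(self) -> EmissionModel:
        if self.beta_params is not None:
            return EmissionModel.beta_pair(*self.beta_params)
        f0, f1 = betas_from_overlap(self.overlap, self.shape_sum)
        return EmissionModel(f0, f1)

    def _sampler(self) -> Callable[[np.random.Generator], float]:
        if self.branch_sampler is not None:
            return self.branch_sampler
        return lognormal_branch_sampler(cutoff=self.depth_cutoff)


@dataclass
class SimulatedTree:
    tree: RootedTree
    states: np.ndarray  # true state per node, postorder-indexed
    scores: dict[str, float] = field(default_factory=dict)

    def leaf_states(self) -> dict[str, int]:
        return {n.name: int(self.states[n.index]) for n in self.tree.leaves}

    def true_events(self) -> np.ndarray:
        """Per-branch truth: parent state != child state (root entry False)."""
        out = np.zeros(self.tree.n_nodes, dtype=bool)
        for node in self.tree.postorder():
            if node.parent is not None:
                out[node.index] = (
                    self.states[node.index] != self.states[node.parent.index]
                )
        return out


# -- generation -------------------------------------------------------------


def sample_tree(config: SimulationConfig, rng: np.random.Generator) -> SimulatedTree:
    """Grow one random tree and evolve true states down it.

    The root draws its state from the equilibrium distribution; every child
    node draws a branch length, becomes a leaf if its root distance exceeds
    the cutoff (else bifurcates), and draws its state from its parent's via
    the branch transition probability.
    """
    draw = config._sampler()
    rates = config.rates
    pi0, _ = rates.equilibrium()

    root = Node(name=None, length=0.0)
    root_state = 0 if rng.random() < pi0 else 1
    states_by_node: dict[int, int] = {id(root): root_state}
    leaf_counter = 0
    n_nodes = 1
    # (node, its root distance, its state)
    stack: list[tuple[Node, float, int]] = [(root, 0.0, root_state)]
    while stack:
        parent, depth, pstate = stack.pop()
        for _ in range(2):
            t = draw(rng)
            child = Node(length=t)
            child_depth = depth + t
            p_same = rates.transition_probability(pstate, pstate, t)
            cstate = pstate if rng.random() < p_same else 1 - pstate
            parent.add_child(child)
            states_by_node[id(child)] = cstate
            n_nodes += 1
            if n_nodes > config.max_nodes_per_tree:
                raise RuntimeError(
                    "simulated tree exceeded max_nodes_per_tree; the branch "
                    "lengths are too short for the depth cutoff"
                )
            if child_depth > config.depth_cutoff:
                leaf_counter += 1
                child.name = f"t{leaf_counter}"
            else:
                stack.append((child, child_depth, cstate))

    tree = RootedTree(root)
    states = np.array([states_by_node[id(n)] for n in tree.postorder()], dtype=np.int64)
    return SimulatedTree(tree=tree, states=states)


def emit_scores(
    sim: SimulatedTree, model: EmissionModel, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one score per leaf from its true state's density (in place)."""
    scores: dict[str, float] = {}
    for leaf in sim.tree.leaves:
        density = model.pair_for(leaf.name)[int(sim.states[leaf.index])]
        if isinstance(density, BetaDensity):
            scores[leaf.name] = float(rng.beta(density.a, density.b))
        elif hasattr(density, "value"):  # point mass: score equals the state
            scores[leaf.name] = float(density.value)
        else:
            raise ValueError(f"cannot sample from {type(density).__name__}")
    sim.scores = scores
    return scores


def simulate_dataset(config: SimulationConfig) -> list[SimulatedTree]:
    """The full dataset for one study condition, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    model = config.emission_model()
    out = []
    for _ in range(config.n_trees):
        sim = sample_tree(config, rng)
        emit_scores(sim, model, rng)
        out.append(sim)
    return out


# -- overlap-parameterized beta pair ----------------------------------------


def overlap_coefficient(f0, f1, n_grid: int = 20_001) -> float:
    """∫ min(f0, f1) over the shared support, by trapezoidal quadrature."""
    lo = max(f0.support[0], f1.support[0])
    hi = min(f0.support[1], f1.support[1])
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("overlap quadrature needs finite shared support")
    pad = 1e-9 * (hi - lo)
    x = np.linspace(lo + pad, hi - pad, n_grid)
    y = np.minimum([f0.pdf(v) for v in x], [f1.pdf(v) for v in x])
    return float(integrate.trapezoid(y, x))


def betas_from_overlap(
    overlap: float, shape_sum: float = 10.0
) -> tuple[BetaDensity, BetaDensity]:
    """Mirrored pair Beta(a, b), Beta(b, a) with a + b fixed and the target
    overlap coefficient, solved by 1-D root search on a.

    The first (state 0) component has the lower mean. Larger overlap means a
    closer to b; overlap → 1 degenerates to identical densities.
    """
    if not 0.01 <= overlap <= 0.99:
        raise ValueError("overlap target must lie in [0.01, 0.99]")

    def gap(a: float) -> float:
        f0 = BetaDensity(a, shape_sum - a)
        f1 = BetaDensity(shape_sum - a, a)
        return overlap_coefficient(f0, f1, n_grid=4001) - overlap

    lo, hi = 0.05, shape_sum / 2.0 - 1e-6
    if gap(lo) > 0:
        raise ValueError(
            f"overlap {overlap} unattainable with shape sum {shape_sum}"
        )
    a = float(optimize.brentq(gap, lo, hi, xtol=1e-10))
    return BetaDensity(a, shape_sum - a), BetaDensity(shape_sum - a, a)


# -- metrics & benchmark ----------------------------------------------------


@dataclass
class MethodReport:
    method: str
    node_accuracy: float  # internal nodes only
    leaf_accuracy: float
    total_accuracy: float
    n_events_called: int
    expected_events: float
    normalized_event_count: float  # called events / total branch length
    normalized_expected_count: float
    event_mcc: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class BenchmarkReport:
    config: SimulationConfig
    methods: dict[str, MethodReport]
    true_event_count: int = 0
    true_normalized_count: float = 0.0
    total_branch_length: float = 0.0
    n_trees: int = 0
    n_nodes: int = 0
    n_leaves: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([m.to_dict() for m in self.methods.values()])

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "n_nodes": self.n_nodes,
            "n_leaves": self.n_leaves,
            "total_branch_length": self.total_branch_length,
            "true_event_count": self.true_event_count,
            "true_normalized_count": self.true_normalized_count,
            "methods": {k: m.to_dict() for k, m in self.methods.items()},
        }


def _safe_mcc(truth: np.ndarray, pred: np.ndarray) -> float:
    if truth.size == 0:
        return 0.0
    if len(np.unique(truth)) < 2 or len(np.unique(pred)) < 2:
        # a constant vector has no correlation to measure
        if not np.array_equal(np.unique(truth), np.unique(pred)):
            warnings.warn(
                "event MCC undefined (a constant label vector); reporting 0.0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(truth, pred))


def _decode_method(
    method: str,
    sim: SimulatedTree,
    rates: RateParams,
    model: EmissionModel,
    threshold: float,
) -> tuple[DecodingResult, np.ndarray]:
    """Run one reconstruction; returns (result, per-branch event calls)."""
    if method == "thmm":
        res = decode(sim.tree, rates, model, sim.scores)
        events = res.called_events()
    elif method == "dumb":
        res = dumb_decode(sim.tree, rates, discretize(sim.scores, threshold))
        events = _state_change_events(res)
    elif method == "known":
        res = dumb_decode(sim.tree, rates, sim.leaf_states())
        events = _state_change_events(res)
    else:
        raise ValueError(f"unknown method {method!r}; pick from {METHODS}")
    return res, events


def _state_change_events(res: DecodingResult) -> np.ndarray:
    """Branch events as state changes in the per-node posterior-MAP states."""
    states = res.posterior_states
    out = np.zeros(res.tree.n_nodes, dtype=bool)
    for node in res.tree.postorder():
        if node.parent is not None:
            out[node.index] = states[node.index] != states[node.parent.index]
    return out


def benchmark(
    config: SimulationConfig,
    methods: Sequence[str] = METHODS,
) -> BenchmarkReport:
    """Simulate one dataset and score each reconstruction method against it.

    Decoding uses the generating rates and (for "thmm") the generating
    densities — the best case for every method, isolating what the score
    information itself is worth. Events for "thmm" are branches with event
    posterior > 0.5; the discrete modes count state changes in their
    posterior-MAP reconstruction. MCC pools branch-level event labels over
    the whole dataset.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; pick from {METHODS}")
    dataset = simulate_dataset(config)
    rates = config.rates
    model = config.emission_model()
    threshold = derive_threshold(model, rates)

    truth_states: list[np.ndarray] = [sim.states for sim in dataset]
    leaf_mask = [
        np.array([n.is_leaf for n in sim.tree.postorder()]) for sim in dataset
    ]
    truth_events = [sim.true_events() for sim in dataset]
    branch_mask = [
        np.array([not n.is_root for n in sim.tree.postorder()]) for sim in dataset
    ]
    total_length = sum(sim.tree.total_branch_length() for sim in dataset)
    true_event_count = int(sum(ev.sum() for ev in truth_events))

    reports: dict[str, MethodReport] = {}
    for method in methods:
        node_hits = node_n = leaf_hits = leaf_n = 0
        called: list[np.ndarray] = []
        expected = 0.0
        for sim, states, lmask, bmask in zip(
            dataset, truth_states, leaf_mask, branch_mask
        ):
            res, events = _decode_method(method, sim, rates, model, threshold)
            pred = res.posterior_states
            ok = pred == states
            node_hits += int(ok[~lmask].sum())
            node_n += int((~lmask).sum())
            leaf_hits += int(ok[lmask].sum())
            leaf_n += int(lmask.sum())
            called.append(events[bmask])
            expected += float(np.nansum(res.event_posterior))
        pred_events = np.concatenate(called)
        true_events = np.concatenate(
            [ev[bm] for ev, bm in zip(truth_events, branch_mask)]
        )
        n_called = int(pred_events.sum())
        reports[method] = MethodReport(
            method=method,
            node_accuracy=node_hits / node_n,
            leaf_accuracy=leaf_hits / leaf_n,
            total_accuracy=(node_hits + leaf_hits) / (node_n + leaf_n),
            n_events_called=n_called,
            expected_events=expected,
            normalized_event_count=n_called / total_length,
            normalized_expected_count=expected / total_length,
            event_mcc=_safe_mcc(true_events, pred_events),
        )

    return BenchmarkReport(
        config=config,
        methods=reports,
        true_event_count=true_event_count,
        true_normalized_count=true_event_count / total_length,
        total_branch_length=total_length,
        n_trees=len(dataset),
        n_nodes=int(sum(s.size for s in truth_states)),
        n_leaves=int(sum(m.sum() for m in leaf_mask)),
    )


# -- grey zone --------------------------------------------------------------


def prior_leaf_probabilities(
    model: EmissionModel,
    rates: RateParams,
    scores: Mapping[str, float],
) -> dict[str, float]:
    """Single-leaf state-1 probability from the score alone (no tree):
    pi1·B(s|1) / (pi0·B(s|0) + pi1·B(s|1)). Missing scores get pi1."""
    pi0, pi1 = rates.equilibrium()
    out: dict[str, float] = {}
    for leaf, s in scores.items():
        if s is None or (isinstance(s, float) and math.isnan(s)):
            out[leaf] = pi1
            continue
        w0 = pi0 * model.density(0, s, leaf)
        w1 = pi1 * model.density(1, s, leaf)
        out[leaf] = w1 / (w0 + w1)
    return out


@dataclass
class GreyZoneCounts:
    n_total: int
    n_prior_in_band: int
    n_posterior_in_band: int


def grey_zone_counts(
    prior: Mapping[str, float] | Sequence[float],
    posterior: Mapping[str, float] | Sequence[float],
    band: tuple[float, float] = (0.4, 0.6),
) -> GreyZoneCounts:
    """How many leaves sit in the ambiguous probability band before and
    after tree-informed decoding. The band is closed; it is symmetric in
    the state, so state-0 and state-1 probabilities give the same counts.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"malformed band {band}")
    if isinstance(prior, Mapping):
        if set(prior) != set(posterior):
            raise ValueError("prior and posterior leaf sets differ")
        keys = sorted(prior)
        p = np.array([prior[k] for k in keys], dtype=float)
        q = np.array([posterior[k] for k in keys], dtype=float)
    else:
        p = np.asarray(prior, dtype=float)
        q = np.asarray(posterior, dtype=float)
        if p.shape != q.shape:
            raise ValueError("prior and posterior lengths differ")
    return GreyZoneCounts(
        n_total=int(p.size),
        n_prior_in_band=int(np.sum((p >= lo) & (p <= hi))),
        n_posterior_in_band=int(np.sum((q >= lo) & (q <= hi))),
    )
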