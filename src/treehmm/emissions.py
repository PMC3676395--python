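"""Per-state score emission densities B(s | state) and their estimation.

A leaf's hidden binary state (feature absent = 0, present = 1) is observed
only through a continuous prediction score; each state has a score density.
This module provides the density families, EM fitting of a two-component
beta mixture to a pooled score sample, and the derivation of the score
threshold used by the discrete (dumb) decoding mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .phylo import RateParams

__all__ = [
    "BetaDensity",
    "NormalDensity",
    "HistogramDensity",
    "PointMass",
    "EmissionModel",
    "BetaMixtureFit",
    "fit_beta_mixture",
    "derive_threshold",
    "discretize",
    "read_scores_tsv",
]

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class BetaDensity:
    """Beta(a, b) density on [0, 1]."""

    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be > 0")

    support = (0.0, 1.0)

    def log_pdf(self, s: float) -> float:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} outside beta support [0, 1]")
        s = min(max(s, _EPS), 1.0 - _EPS)
        return (
            (self.a - 1.0) * math.log(s)
            + (self.b - 1.0) * math.log1p(-s)
            - special.betaln(self.a, self.b)
        )

    def pdf(self, s: float) -> float:
        return math.exp(self.log_pdf(s))

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def spec(self) -> dict:
        return {"family": "beta", "params": {"a": self.a, "b": self.b}}


@dataclass(frozen=True)
class NormalDensity:
    """Gaussian score density (used e.g. for PWM Z-scores)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    support = (-math.inf, math.inf)

    def log_pdf(self, s: float) -> float:
        z = (s - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    def pdf(self, s: float) -> float:
        return math.exp(self.log_pdf(s))

    def mean(self) -> float:
        return self.mu

    def spec(self) -> dict:
        return {"family": "normal", "params": {"mu": self.mu, "sigma": self.sigma}}


class HistogramDensity:
    """Empirical density from a normalized histogram (piecewise constant)."""

    def __init__(self, bin_edges: Sequence[float], densities: Sequence[float]):
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.densities = np.asarray(densities, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.densities) + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        widths = np.diff(self.bin_edges)
        mass = float(np.sum(widths * self.densities))
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"histogram mass {mass} != 1")
        self.support = (float(self.bin_edges[0]), float(self.bin_edges[-1]))

    @classmethod
    def from_sample(cls, sample: Sequence[float], bins: int = 50) -> "HistogramDensity":
        dens, edges = np.histogram(np.asarray(sample, float), bins=bins, density=True)
        return cls(edges, dens)

    def pdf(self, s: float) -> float:
        lo, hi = self.support
        if not lo <= s <= hi:
            raise ValueError(f"score {s} outside histogram support [{lo}, {hi}]")
        k = min(np.searchsorted(self.bin_edges, s, side="right") - 1,
                len(self.densities) - 1)
        return float(self.densities[max(k, 0)])

    def log_pdf(self, s: float) -> float:
        p = self.pdf(s)
        return math.log(p) if p > 0 else -math.inf

    def mean(self) -> float:
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.sum(mids * self.densities * np.diff(self.bin_edges)))

    def spec(self) -> dict:
        return {
            "family": "histogram",
            "params": {
                "bin_edges": self.bin_edges.tolist(),
                "densities": self.densities.tolist(),
            },
        }


@dataclass(frozen=True)
class PointMass:
    """Degenerate emission for directly observed discrete states.

    The "score" is the observed 0/1 state itself: probability 1 when it
    equals ``value``, 0 otherwise. Decoding with a point-mass pair is exactly
    the classical discrete ancestral-reconstruction setting (dumb mode).
    """

    value: int

    support = (0.0, 1.0)

    def pdf(self, s: float) -> float:
        if s not in (0, 1, 0.0, 1.0):
            raise ValueError(f"point-mass emission expects a 0/1 observation, got {s}")
        return 1.0 if int(s) == self.value else 0.0

    def log_pdf(self, s: float) -> float:
        return 0.0 if self.pdf(s) == 1.0 else -math.inf

    def mean(self) -> float:
        return float(self.value)

    def spec(self) -> dict:
        return {"family": "point_mass", "params": {"value": self.value}}


def _density_from_spec(spec: Mapping) -> object:
    family = spec["family"]
    params = spec.get("params", {})
    if family == "beta":
        return BetaDensity(params["a"], params["b"])
    if family == "normal":
        return NormalDensity(params["mu"], params["sigma"])
    if family == "histogram":
        return HistogramDensity(params["bin_edges"], params["densities"])
    if family == "point_mass":
        return PointMass(int(params["value"]))
    raise ValueError(f"unknown density family {family!r}")


class EmissionModel:
    """Pair of per-state score densities, optionally specialized per leaf.

    ``densities`` holds the shared (state0, state1) pair; ``per_leaf`` may
    map a leaf name to its own pair (the binding-site application uses a
    per-gene background density). A missing score contributes emission 1 for
    every state, i.e. the leaf is marginalized.
    """

    def __init__(
        self,
        state0,
        state1,
        weights: tuple[float, float] | None = None,
        per_leaf: Mapping[str, tuple] | None = None,
        threshold: float | None = None,
    ):
        self.densities = (state0, state1)
        if weights is not None:
            if abs(weights[0] + weights[1] - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            weights = (float(weights[0]), float(weights[1]))
        self.weights = weights
        self.per_leaf = dict(per_leaf) if per_leaf else {}
        self.threshold = threshold

    # -- constructors ------------------------------------------------------

    @classmethod
    def point_mass(cls) -> "EmissionModel":
        return cls(PointMass(0), PointMass(1))

    @classmethod
    def beta_pair(cls, a0: float, b0: float, a1: float, b1: float) -> "EmissionModel":
        return cls(BetaDensity(a0, b0), BetaDensity(a1, b1))

    @classmethod
    def uniform(cls) -> "EmissionModel":
        """Uninformative emissions: every score equally likely in both states."""
        return cls(BetaDensity(1.0, 1.0), BetaDensity(1.0, 1.0))

    # -- evaluation --------------------------------------------------------

    def pair_for(self, leaf: str | None) -> tuple:
        if leaf is not None and leaf in self.per_leaf:
            return self.per_leaf[leaf]
        return self.densities

    def log_density(self, state: int, score: float, leaf: str | None = None) -> float:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            return 0.0  # missing observation: marginalized
        return self.pair_for(leaf)[state].log_pdf(score)

    def density(self, state: int, score: float, leaf: str | None = None) -> float:
        return math.exp(self.log_density(state, score, leaf))

    @property
    def is_point_mass(self) -> bool:
        return all(isinstance(d, PointMass) for d in self.densities)

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "state0": self.densities[0].spec(),
            "state1": self.densities[1].spec(),
        }
        if self.weights is not None:
            doc["weights"] = list(self.weights)
        if self.threshold is not None:
            doc["threshold"] = self.threshold
        if self.per_leaf:
            doc["per_leaf"] = {
                leaf: {"state0": pair[0].spec(), "state1": pair[1].spec()}
                for leaf, pair in self.per_leaf.items()
            }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EmissionModel":
        doc = json.loads(text)
        per_leaf = {
            leaf: (_density_from_spec(d["state0"]), _density_from_spec(d["state1"]))
            for leaf, d in doc.get("per_leaf", {}).items()
        }
        return cls(
            _density_from_spec(doc["state0"]),
            _density_from_spec(doc["state1"]),
            weights=tuple(doc["weights"]) if "weights" in doc else None,
            per_leaf=per_leaf,
            threshold=doc.get("threshold"),
        )


# -- beta-mixture fitting ---------------------------------------------------


@dataclass
class BetaMixtureFit:
    """Result of EM on a two-component beta mixture.

    The component with the lower mean is state 0 (in the intended
    applications a higher score signals feature presence).
    """

    model: EmissionModel
    log_likelihood: float
    loglik_trace: list[float] = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    degenerate_component: int | None = None
    # BIC improvement of two components over the single-beta MLE; negative
    # means the sample does not support a second component
    bic_gain: float = float("nan")

    @property
    def weights(self) -> tuple[float, float]:
        return self.model.weights


def _weighted_beta_mle(x, logx, log1mx, w, start: BetaDensity) -> BetaDensity:
    """Maximize sum_i w_i log Beta(x_i; a, b) over (a, b), warm-started.

    Falls back to the start point if the optimizer fails to improve — this
    keeps the EM objective monotone even on hard steps.
    """
    wsum = w.sum()
    if wsum <= 0:
        return start
    mlx = float(np.dot(w, logx) / wsum)
    ml1x = float(np.dot(w, log1mx) / wsum)

    def neg(theta):
        a, b = np.exp(theta)
        return -(wsum * ((a - 1) * mlx + (b - 1) * ml1x - special.betaln(a, b)))

    theta0 = np.log([start.a, start.b])
    res = optimize.minimize(neg, theta0, method="L-BFGS-B")
    if res.fun <= neg(theta0):
        a, b = np.exp(res.x)
        return BetaDensity(float(a), float(b))
    return start


def _moment_beta(x: np.ndarray) -> BetaDensity:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-6)
    common = max(m * (1 - m) / v - 1.0, 0.05)
    return BetaDensity(max(m * common, 0.05), max((1 - m) * common, 0.05))


def fit_beta_mixture(
    scores: Sequence[float],
    max_iter: int = 500,
    tol: float = 1e-8,
    degenerate_weight: float = 1e-3,
) -> BetaMixtureFit:
    """Fit w0·Beta(a0,b0) + w1·Beta(a1,b1) to scores in [0, 1] by EM.

    Scores equal to 0 or 1 are shrunk inward by machine epsilon before
    fitting. Components are relabeled afterwards so the lower-mean component
    is state 0. Raises on fewer than 50 scores or a degenerate (constant)
    sample; non-convergence returns the best iterate with
    ``converged=False``.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or len(x) < 50:
        raise ValueError(f"need at least 50 scores, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x > 1):
        raise ValueError("scores must be finite and within [0, 1]")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate data: all scores are (nearly) equal")
    x = np.clip(x, _EPS, 1.0 - _EPS)
    logx, log1mx = np.log(x), np.log1p(-x)

    # split at the median for a deliberately rough but deterministic start
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    if len(hi) < 2:  # extremely skewed sample
        lo, hi = x[:-2], x[-2:]
    comps = [_moment_beta(lo), _moment_beta(hi)]
    w = np.array([len(lo), len(hi)], dtype=float)
    w /= w.sum()

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        logp = np.stack(
            [
                np.log(w[k])
                + (comps[k].a - 1) * logx
                + (comps[k].b - 1) * log1mx
                - special.betaln(comps[k].a, comps[k].b)
                for k in (0, 1)
            ]
        )
        m = logp.max(axis=0)
        ll = float(np.sum(m + np.log(np.exp(logp - m).sum(axis=0))))
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        resp = np.exp(logp - m)
        resp /= resp.sum(axis=0)
        # M-step
        w = resp.sum(axis=1) / len(x)
        w = np.clip(w, 1e-12, None)
        w /= w.sum()
        comps = [
            _weighted_beta_mle(x, logx, log1mx, resp[k], comps[k]) for k in (0, 1)
        ]

    order = np.argsort([c.mean() for c in comps])
    comps = [comps[order[0]], comps[order[1]]]
    w = w[order]
    # a sample from a single density is fit almost as well by one beta; on
    # that unidentifiable ridge EM keeps two arbitrary components, so flag
    # degeneracy by a BIC comparison against the single-component MLE
    # (3 extra parameters) as well as by outright weight collapse
    single = _weighted_beta_mle(x, logx, log1mx, np.ones_like(x), _moment_beta(x))
    ll_single = float(
        np.sum((single.a - 1) * logx + (single.b - 1) * log1mx)
        - len(x) * special.betaln(single.a, single.b)
    )
    bic_gain = 2.0 * (trace[-1] - ll_single) - 3.0 * math.log(len(x))
    degenerate = None
    if w.min() < degenerate_weight or bic_gain < 0:
        degenerate = int(np.argmin(w))
    model = EmissionModel(comps[0], comps[1], weights=(float(w[0]), float(w[1])))
    return BetaMixtureFit(
        model=model,
        log_likelihood=trace[-1],
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        degenerate_component=degenerate,
        bic_gain=bic_gain,
    )


# -- threshold / discretization ---------------------------------------------


def derive_threshold(
    model: EmissionModel, rates: RateParams, rule: str = "posterior"
) -> float:
    """Score threshold t* separating the two states for discrete decoding.

    ``rule="posterior"`` (default) solves pi0·B(t*|0) = pi1·B(t*|1): the
    score at which the single-leaf state posterior under equilibrium priors
    crosses 1/2. ``rule="density"`` drops the priors and solves
    B(t*|0) = B(t*|1). If several crossings exist the one between the two
    component means is returned.
    """
    f0, f1 = model.densities
    if isinstance(f0, PointMass) or isinstance(f1, PointMass):
        raise ValueError("threshold requires continuous per-state densities")
    if rule == "posterior":
        pi0, pi1 = rates.equilibrium()
    elif rule == "density":
        pi0 = pi1 = 0.5
    else:
        raise ValueError(f"unknown rule {rule!r}")

    lo = max(f0.support[0], f1.support[0])
    hi = min(f0.support[1], f1.support[1])
    if not (math.isfinite(lo) and math.isfinite(hi)):
        lo, hi = min(f0.mean(), f1.mean()) - 10, max(f0.mean(), f1.mean()) + 10
    pad = 1e-9 * (hi - lo)
    grid = np.linspace(lo + pad, hi - pad, 4097)

    def g(s: float) -> float:
        return (math.log(pi1) + f1.log_pdf(s)) - (math.log(pi0) + f0.log_pdf(s))

    values = np.array([g(s) for s in grid])
    if np.all(values == 0.0):  # identical weighted densities: no threshold
        raise ValueError(
            "no threshold: the weighted state densities never cross "
            "(nested or identical densities)"
        )
    exact = np.nonzero(values == 0.0)[0]
    if len(exact):  # a grid point is itself a root (e.g. mirrored densities)
        m_lo, m_hi = sorted((f0.mean(), f1.mean()))
        inside = [i for i in exact if m_lo <= grid[i] <= m_hi] or list(exact)
        return float(grid[inside[0]])
    sign_change = np.nonzero(np.sign(values[:-1]) * np.sign(values[1:]) < 0)[0]
    if len(sign_change) == 0:
        raise ValueError(
            "no threshold: the weighted state densities never cross "
            "(nested or identical densities)"
        )
    m_lo, m_hi = sorted((f0.mean(), f1.mean()))
    brackets = [(grid[i], grid[i + 1]) for i in sign_change]
    preferred = [
        b for b in brackets if m_lo <= 0.5 * (b[0] + b[1]) <= m_hi
    ] or brackets
    a, b = preferred[0]
    return float(optimize.brentq(g, a, b, xtol=1e-12))


def discretize(scores: Mapping[str, float], threshold: float) -> dict[str, int]:
    """Map scores to 0/1 leaf states: 1 iff score > threshold (ties → 0).

    Missing scores (None/NaN) stay missing.
    """
    out: dict[str, int] = {}
    for leaf, s in scores.items():
        if s is None or (isinstance(s, float) and math.isnan(s)):
            out[leaf] = None
        else:
            out[leaf] = int(s > threshold)
    return out


def read_scores_tsv(path) -> dict[str, float]:
    """Read a leaf→score table: first column leaf name, second the score.

    Extra columns are ignored; 'NA'/'NaN'/'' mark a missing score. A header
    line is detected by a non-numeric second field.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("scores TSV needs at least two columns")
    start = 0
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1  # header row
    out: dict[str, float] = {}
    for _, row in df.iloc[start:].iterrows():
        name = str(row.iloc[0])
        raw = row.iloc[1]
        if raw is None or str(raw).strip() in ("", "NA", "NaN", "nan"):
            out[name] = math.nan
        else:
            out[name] = float(raw)
    return out
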