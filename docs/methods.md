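# Methods

## Model

A binary trait (feature absent = 0, present = 1) evolves along a rooted
phylogeny with branch lengths under a two-state continuous-time Markov
chain with gain rate λ01 and loss rate λ10 (per unit branch length, in the
tree's own time units — no rescaling is applied). The transition
probability over a branch of length t is the standard two-state solution

    P_ij(t) = π_j + (δ_ij − π_j) · exp(−(λ01 + λ10) t),

with stationary distribution π = (λ10, λ01)/(λ01 + λ10). π is also the
default root prior; the decoding functions accept an explicit
``root_prior`` override for sensitivity analysis, but the equilibrium
prior is the model's own assumption and the CLI does not expose the knob.

The trait is not observed directly. Each leaf carries a continuous
prediction score s (e.g. a signal-peptide D-score or a PWM best-hit
score), linked to the hidden state by per-state emission densities
B(s | σ). This makes the whole object a hidden Markov model on the tree:
transitions along branches, emissions at the leaves. With point-mass
emissions (the observed "score" is the 0/1 state itself) the model reduces
exactly to the classical discrete ancestral-reconstruction setting; the
package calls this *dumb mode* and routes it through the same code paths.

Evolution on different branches is conditionally independent given the
parent states, so the likelihood of a full assignment σ of states to nodes
factorizes into the root prior, one transition factor per branch, and one
emission factor per leaf. All algorithms below are written as products
over an arbitrary child list, so multifurcating trees are supported even
though the binary case is the common one.

## Algorithms

**Total likelihood.** Felsenstein-style pruning: subtree likelihoods
("down" variables) are combined leaf-to-root. Per-node rescaling (divide
by the per-node maximum, accumulate the log of the scale) keeps the linear
recursion exact in log-likelihood while avoiding underflow on large trees.

**Tree Viterbi.** A max-product version of the same recursion in
log-space, with per-(node, parent-state) traceback pointers, yields the
jointly most probable assignment of states to *all* nodes — including the
leaves, whose states are free to disagree with a naive reading of their
scores when the phylogenetic context demands it. Ties are broken toward
state 0 at every maximization, deterministically.

**Up-down posterior decoding.** The tree analogue of forward-backward.
"Up" variables (rest-of-tree likelihoods) are propagated root-to-leaf,
combining the parent's up variable with the down messages of the other
children. Node posteriors are up·down/P(D); the per-branch joint over
(parent state, child state) combines the parent's up variable, its other
children's messages, the branch transition and the child's down variable.
Gain is joint(0,1), loss is joint(1,0), and an "event" on a branch is
their sum. The expected event count of a tree is the sum of event
posteriors over branches.

**Exhaustive oracle.** For trees up to 16 nodes an enumeration over all
2^n assignments computes the same quantities by direct summation. It
exists purely as an independent check: the test suite requires agreement
with the recursions to 1e-10 relative error on hundreds of random
instances (random topologies with 2–6 leaves, occasional multifurcations,
branch lengths in [0, 1], rates in [0.05, 5], beta or point-mass
emissions, with and without missing observations).

**Missing data.** A leaf with a missing score (NaN/None) contributes
emission 1 for every state and is thereby marginalized — the standard HMM
convention. A leaf absent from the score table entirely is an error, so
silent data loss is impossible.

## Emission models and the discretization threshold

Supported families: beta (support [0, 1]), normal, piecewise-constant
histogram, and point mass. Scores outside a family's support are errors,
not clamped. Models may be specialized per leaf (the binding-site use case
defines a separate background density per gene); the default is one shared
pair.

When only a pooled score sample is available, a two-component beta mixture
is fitted by EM. The M-step maximizes each component's weighted
log-likelihood numerically (L-BFGS on log-shape parameters, warm-started
at the current values, reverting if the optimizer fails to improve), which
preserves EM's monotone log-likelihood. Convergence is declared when the
log-likelihood changes by less than 1e-8, with a 500-iteration cap; the
best iterate is returned either way. Components are relabeled so the
lower-mean component is state 0, matching the convention that a higher
score signals feature presence. Boundary scores are shrunk inward by
machine epsilon before fitting.

Degeneracy (a sample that does not support two components) is *not*
detected by waiting for a weight to collapse: EM started from a balanced
deterministic split stays on the unidentifiable ridge with two overlapping
components whose mixture matches the single density, and weight collapse
would depend on initialization. Instead the fit is compared against the
single-beta maximum likelihood by BIC (three extra parameters); a negative
BIC gain flags the lower-weight component as degenerate. This fires
reliably on single-component data and never on well-separated mixtures.

The score threshold t\* used by discrete decoding solves
π0·B(t\*|0) = π1·B(t\*|1) — the score at which the single-leaf posterior
under equilibrium weighting crosses 1/2 — by bracketed root search, taking
the crossing between the two component means if several exist. An
unweighted density-crossing rule (B(t\*|0) = B(t\*|1)) is available via
`rule="density"`; both are natural conventions and the choice is exposed
rather than hidden. Discretization assigns state 1 iff s > t\*; an exact
tie goes to state 0, deterministically.

## Rate inference

ML: bounded L-BFGS on log-rates (bounds 1e-3 to 1e2 on the natural scale)
from three spread-out starts, with an optional symmetric (λ01 = λ10)
constraint.

Bayesian: Metropolis–Hastings with a Gaussian random walk on log-rates.
The model itself leaves the prior and proposal unspecified, so they are
explicit configuration with visible defaults: independent uniform priors
on log10-rate over [−3, 2] (stated directly on the log scale, so no
Jacobian bookkeeping is needed), chain length 20,000, burn-in 5,000,
thinning 10, initial proposal std 0.3. The proposal scale is multiplied
toward a 20–40% acceptance window every 100 iterations *during burn-in
only* and then frozen, preserving detailed balance for the retained
samples. Everything is reproducible from the seed. With the likelihood
forced constant the sampler demonstrably reproduces the prior (tested by
Kolmogorov–Smirnov distance).

Because ML and MCMC evaluate the same dataset likelihood thousands of
times with only the rates changing, the dataset is flattened once into
postorder arrays (parent index, branch length, per-node linear emissions)
and evaluated by a numba-compiled pruning kernel, with a pure-Python
fallback when numba is absent. The kernel is tested for exact agreement
with the reference decoder.

## Simulation study

`SimulationConfig` defaults are the anchor condition of the benchmark:
symmetric rate 0.2, score-density overlap 0.19, depth cutoff 0.5, 400
trees. Trees are grown by recursive bifurcation: each new branch draws a
length; a lineage becomes a leaf once its root distance exceeds the
cutoff. The root state is drawn from π and each child's state from its
parent's through P(t). Branch lengths default to a
log-normal(μ = −2.5, σ = 1) truncated to (0, cutoff] — a synthetic
stand-in for an empirical branch-length distribution, chosen to give trees
of a few dozen to ~100 leaves under the default cutoff; any empirical
sample can be plugged in via `empirical_branch_sampler`.

The two score densities are a mirrored pair Beta(a, b) / Beta(b, a) with
fixed shape sum a + b = 10, parameterized by their overlap coefficient
∫ min(f0, f1) (computed by quadrature; the definition is a pluggable
function). A 1-D root search finds the a achieving the target overlap;
at overlap 0.19 the solved pair is approximately Beta(3.04, 6.96) and its
mirror, and the leaf-discretization error rate is overlap/2 ≈ 9.5%.

The benchmark decodes each simulated tree three ways: "thmm" from the raw
scores with the generating densities, "dumb" from leaves discretized at
the derived threshold, and "known" from the true leaf states — the last
two bracket what any discrete-input method can achieve. All methods use
the generating rates; the comparison isolates the value of the score
information itself. Metrics, pooled across the dataset: proportion of
correctly restored states (internal nodes, leaves, and all nodes), the
number of reconstructed events normalized by total branch length
(alongside the true value), and the Matthews correlation coefficient of
per-branch binary event labels. Events are called, for score decoding, as
branches with event posterior > 0.5 and, for the discrete modes, as state
changes in the per-node posterior-MAP reconstruction; expected event
counts (sums of posteriors) are reported alongside because either
tabulation is defensible. States for accuracy are the per-node posterior
MAP in all modes. An MCC over constant label vectors is reported as 0
with a warning.

The grey-zone summary counts leaves whose state probability lies in the
closed band [0.4, 0.6] before decoding (single-leaf Bayes with equilibrium
weights: π1·B(s|1)/Σ) and after (tree-informed posterior). On simulated
data the posterior count is a fraction of the prior count — the tree
context resolves most near-threshold scores.

## Problem sizes and numerical choices

The acceptance-level checks run the anchor condition at its full 400
trees (≈90,000 nodes) and a 3×3 grid of rates {0.1, 0.2, 0.4} × overlaps
{0.10, 0.19, 0.30} at 100 trees per cell over 10 seeds; oracle-equivalence
checks use 200 random ≤6-leaf instances. These sizes keep the full suite
in the minutes range on one CPU while leaving the Monte-Carlo margins of
the qualitative orderings wide (all three orderings — accuracy, event
calibration, event MCC — held in 10/10 seeds at every grid cell when the
defaults were frozen).

Other numerical choices: probabilities are accumulated with per-node
rescaling (exactly equivalent to log-space); Viterbi works natively in
log-space; branch joints are renormalized per branch to absorb float
round-off (≤1e-12); root search tolerances are 1e-10 (overlap solver) and
1e-12 (threshold); zero-length branches are legal (P(0) = I forces zero
event posterior), but a missing branch length in Newick input is an error
unless an explicit default is supplied, because silently assuming zero
changes the inference.

## What the simulations do and do not show

The generator matches the study design it implements: idealized
conditions in which the decoder is given the *true* emission densities
and rates. Real applications must estimate both (the beta-mixture fit and
the MCMC/ML rate inference exist for exactly that), so the reported
accuracy gaps are upper bounds on the advantage of score-based decoding.
Real score distributions need not be beta, real trees are estimated (with
error) rather than known, and scores of neighboring genomes can be
correlated through alignment pipelines in ways the independent-emission
model ignores. Phylogenetic uncertainty (decoding over a set of candidate
trees) and joint tree+trait inference are out of scope.

## Known limitations

- Two states only (the recursions are written over a state index, so a
  K-state extension is a parameter change, but it is untested and not
  exposed).
- No stochastic traceback / joint sampling of full state configurations.
- The Viterbi tie rule (toward state 0) makes the reported MAP assignment
  unique but arbitrary among ties.
- MCMC adapts a single isotropic proposal scale; strongly correlated
  posteriors (tiny datasets) mix slowly, though the defaults are tuned for
  the hundreds-of-trees regime where the posterior is nearly Gaussian.
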