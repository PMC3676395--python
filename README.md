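# treehmm

Ancestral and leaf state reconstruction on a phylogeny when the extant
states are known only through continuous prediction scores.

A common situation in comparative genomics: a prediction program (a
signal-peptide predictor, a PWM scanner, …) assigns each extant genome a
*score* for some binary feature, not the feature itself. Thresholding the
scores and running a classical discrete ancestral-reconstruction method
wastes the information in near-threshold scores and, worse, converts every
borderline misassignment into a spurious evolutionary event. `treehmm`
instead treats the binary feature as the hidden state of a hidden Markov
model on the tree: states at all nodes evolve under a two-state
continuous-time Markov chain, and each leaf emits its observed score
through a per-state density. Decoding then reconstructs states at the
ancestral nodes **and refines the states at the leaves** using the
phylogenetic context.

## Model

* Transition kernel over a branch of length *t*:
  `P_ij(t) = π_j + (δ_ij − π_j)·exp(−(λ01+λ10)t)`, with gain rate λ01,
  loss rate λ10 and equilibrium `π = (λ10, λ01)/(λ01+λ10)` (also the root
  prior).
* Emission densities `B(s|σ)` for score *s* given hidden state σ ∈ {0,1}:
  beta, normal, histogram, per-leaf overrides, or point masses — the last
  reduces the model exactly to classical discrete reconstruction
  ("dumb mode").
* Algorithms: total likelihood by Felsenstein pruning; joint MAP states
  by a tree Viterbi recursion with traceback; per-node posteriors and
  per-branch gain/loss event posteriors by the up-down algorithm (the
  tree analogue of forward–backward); exhaustive enumeration as an
  independent oracle on small trees.
* Inference: λ01, λ10 by bounded ML or Metropolis–Hastings MCMC on
  log-rates; emission densities from pooled scores by two-component
  beta-mixture EM, with a derived discretization threshold
  `π0·B(t*|0) = π1·B(t*|1)` for the discrete baseline.
* A simulation/benchmark harness: random trees grown to a depth cutoff,
  states evolved under the chain, scores emitted from beta densities with
  a controlled overlap coefficient, and three-way method comparison
  (scores vs. discretized vs. true leaf states) on state accuracy,
  normalized event counts and event MCC.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```sh
cat > tree.nwk <<'NWK'
((A:0.1,B:0.12):0.05,(C:0.2,D:0.08):0.1);
NWK
printf 'A\t0.82\nB\t0.77\nC\t0.15\nD\t0.46\n' > scores.tsv
python - <<'PY'
from treehmm import EmissionModel
open("emissions.json", "w").write(EmissionModel.beta_pair(2, 6, 6, 2).to_json())
PY

treehmm decode --tree tree.nwk --scores scores.tsv \
    --emissions emissions.json --rates 0.3,0.3 --out out --stdout
```

prints the run summary

```
{"log_likelihood": -0.5030360373103361, "viterbi_logprob": -1.4404289346552117,
 "expected_event_count": 1.032984925233462, "n_events_called": 0, ...}
```

and writes `out/nodes.tsv`:

```
node_id  node_name  is_leaf  P_state0  P_state1  posterior_state  viterbi_state
0        A          True     0.001353  0.998647  1                1
1        B          True     0.003521  0.996479  1                1
2                   False    0.017882  0.982118  1                1
3        C          True     0.993333  0.006667  0                0
4        D          True     0.594387  0.405613  0                1
5                   False    0.583516  0.416484  0                1
6                   False    0.206634  0.793366  1                1
```

Leaves A and B (high scores) and C (low score) are confidently assigned,
and the root (node 6) is reconstructed as state 1 with probability 0.79.
The interesting row is leaf D: its score 0.46 sits in the grey zone where
the two emission densities overlap, so its posterior stays genuinely
ambiguous (0.41) instead of being forced to whatever side of a threshold
0.46 happens to fall on — and the joint (Viterbi) reconstruction actually
prefers state 1 for it, pulled by its state-1 neighborhood, while the
marginal posterior leans 0. `out/branches.tsv` gives per-branch gain/loss
posteriors (the C branch carries a loss with probability 0.41), and
`out/annotated.nwk` is the input tree with `P1=` annotations.

The other subcommands: `treehmm fit` (ML or MCMC rate inference over a
dataset of trees), `treehmm fit-emissions` (beta-mixture EM on a score
table), `treehmm simulate` and `treehmm benchmark`. Every subcommand is a
thin wrapper over the library API (`treehmm.decode`, `treehmm.mcmc_rates`,
`treehmm.benchmark`, …), which is the more convenient interface from
Python.

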