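# Methods

## Model

Characters evolve along a rooted phylogeny `φ` (branch lengths in expected
substitutions per site) under a stationary continuous-time Markov
substitution model with rate matrix `Q` and equilibrium `π`. Two tip
characters are *phylogenetically identical by descent* (PIBD) when no
substitution event occurs anywhere on the path connecting them through
their most recent common ancestor. PIBD is a statement about events, not
states: the probability of zero events on a branch of length `t` starting
in state `j` is `I_t[j] = exp(t·Q[j,j])`, strictly smaller than the
return probability `P_t[j,j]` for `t > 0`, and the gap is exactly the
multiple-hit mass that makes identity by state uninformative at
saturation.

The novelty score of tip `s` is `w_s = E[1/i_φ(s)]`, where `i_φ(s)` is
the size of the PIBD class of `s` (at least 1). Weights therefore lie in
`[1/N, 1]`, approach `1/N` as all branches shrink to zero (one effective
observation) and `1` as all branches saturate (independent observations).
Their sum `T`, the effective sequence number (ESN), equals the expected
number of PIBD classes among the tips. The conditional score `w_s^D`
replaces `p_s(i)` with `p_s(i | D)` for an observed column `D`; gaps and
ambiguity codes are missing data (flat partial likelihood, still counted
as tips in class sizes).

Assumptions: one character per tip per column, columns independent,
stationarity (root state drawn from `π`), no indel process, no
across-site rate variation. For reversible models the scores are
invariant to root placement, so unrooted (trifurcating-root) Newick
input is accepted and rooted arbitrarily; non-reversible custom models
require genuinely rooted input (`require_rooted=True`).

## Algorithms

**Exact up–down pruning** (`pns.updown`). Messages are arrays
`M[i, j]` over (PIBD count, state). The *up* phase (post-order) computes,
for each node and its subtree, the joint probability of the subtree data
and the number of subtree tips connected to the node by substitution-free
paths, conditional on the node's state: tip initialisation puts mass at
`i = 1`; moving up a branch multiplies by `I_t` for `i ≥ 1` while the
`i = 0` slot additionally absorbs the "at least one event" mass
`P_t − diag(I_t)` applied to the message's marginal; sibling messages
combine by convolution over `i` (disjoint tip sets add). The *down* phase
(pre-order) computes the same quantity for the complement of each
subtree, seeded at the root with `π` at `i = 0` (the empty parent
sub-phylogeny), and the two meet at every tip, giving `p_s(i | D)` after
normalisation. Cost is O(N³) overall; message lengths are capped by the
relevant tip counts, which is what keeps the convolutions quadratic
rather than cubic per node.

Summing any up message over `i` recovers the ordinary Felsenstein partial
likelihood, so the normaliser equals the column likelihood `P(D)`; the
test suite checks this against an independently coded pruning likelihood,
and checks the full distributions against two independent oracles (below).

**Linear-time ESN** (`pns.esn`). `T` equals the expected number of PIBD
classes, and each class can be counted at its root-most member, which
requires a substitution on the branch above it (or the root) and at least
one substitution-free connection to a tip below. With
`a_ν(j) = P(no tip below ν is substitution-free-connected to ν | state j)`
(zero at tips, multiplicative over children internally),

    T = Σ_j π_j (1 − a_ρ(j)) + Σ_{branches b} Σ_j π_j (1 − I_b[j]) (1 − a_child(b)(j)).

This recursion is validated against summed exact weights; the conditional
`T^D` falls back to summing conditional weights.

**Fast approximation** (`pns.fast_pns_weights`).
`w̄_s = 1/E[i_φ(s)]` with
`E[i_φ(s)] = 1 + Σ_{s'≠s} Σ_j π_j exp(Q[j,j]·d(s,s'))`, computed for all
tips at once by one post-order and one pre-order sweep of per-state
no-substitution mass (O(N·B)); the quadratic pairwise sum is kept only as
a test oracle. By Jensen's inequality `w̄_s ≤ w_s`; the bound is tested.
No conditional variant is provided.

**Oracles** (`oracles`). Three independent routes validate the dynamic
program. (1) `enumerate_histories`: fully naive enumeration of every
(state assignment, per-branch indicator) history, feasible to 3 tips.
(2) `brute_force_pibd`: exhaustive enumeration of the `2^branches`
substitution-indicator patterns; for each pattern the tip partition is
fixed and the probability is summed over states exactly by pruning on the
component tree (substitution-free branches contract; substituted branches
carry `P_t − diag(I_t)`), feasible to ~6 tips and itself validated
against (1). (3) Monte-Carlo simulation with explicit Gillespie event
recording — waiting times at rate `−Q[j,j]`, jumps `Q[j,k]/−Q[j,j]` —
because endpoint-only simulation cannot distinguish descent from
coincidental state identity. Conditional simulation either samples all
node states from their joint posterior given the column (up–down
ancestral sampling) and then draws per-branch "no event" with probability
`I_t[j]/P_t[j,j]` where endpoints agree, or uses plain rejection;
rejection refuses columns whose likelihood (its exact acceptance
probability) is below 1e-6.

## Substitution models

`jc69()`, `hky85(kappa, pi)` (κ multiplies transition rates A↔G, C↔T;
defaults κ = 3), `lg()` (standard published LG exchangeabilities and
frequencies, optionally with replaced `π`), and `custom_model` (raw `Q`
or exchangeabilities + `π`). All constructors normalise to one expected
substitution per unit branch length at equilibrium
(`−Σ_j π_j Q[j,j] = 1`), matching branch lengths in substitutions per
site; raw custom matrices can opt out (`normalise=False`). Transition
matrices come from the symmetric eigendecomposition of the
`π^{1/2}`-similarity transform (exact for every reversible model, one
cached decomposition per model), with `scipy.linalg.expm` as the
non-reversible fallback. JC69's closed forms
(`I = e^{−t}`, `P[j,j] = (1+3e^{−4t/3})/4`) are asserted in tests rather
than special-cased in code.

## Downstream inference

Weighted frequencies `p^w(j) = Σ_s w_s δ(j, D_s) / Σ_s w_s` over
non-missing rows (invariant to weight rescaling). The Bayesian layer
approximates the column likelihood by `Π_s π(D_s)^{w_s}`; with a uniform
prior the posterior is Dirichlet with `α_j = 1 + Σ_s w_s δ(j, D_s)` — its
mode is `p^w`, its mean the pseudo-count-smoothed estimate
`α_j/α_0`, its marginals `Beta(α_j, α_0 − α_j)` giving equal-tail
credible intervals (not HPD; the marginal quantile function is the
natural object here). Unlike the point estimate, the posterior is *not*
scale-invariant in the weights: `Σ_s w_s` is the effective evidence mass,
which is precisely the point of using ESN-calibrated weights.
Conservation is reported as `R = log₂B − S_obs` bits with `0·log 0 = 0`.

## Synthetic benchmark

`simstudy` emulates a profiling benchmark: columns evolve independently
on a fixed tree under HKY85 (κ = 3) or LG; 80% of columns share the
background equilibrium (`π(A)=π(T)=0.3, π(C)=π(G)=0.2` for nucleotides)
and 20% are "selected", each with its own equilibrium from a symmetric
Dirichlet (α = 0.1 nucleotides, 0.02 amino acids), the regime split exact
by default. Selected-column rate matrices are rebuilt with the drawn `π`
(fixed κ/exchangeabilities), re-normalised to unit rate, with a 1e-9
frequency floor so the chain stays irreducible. Simulation here is
endpoint sampling (only tip states are recorded). Accuracy is the
per-column Euclidean distance between true and inferred frequency
vectors, summarised as mean and median per scheme, replicate and regime.
The true simulation tree is handed to tree-based schemes; inferring the
tree is deliberately out of scope (a pre-inferred tree can be substituted
by building the config around it).

Two named scenarios fix the study conditions:

* `biased_sampling_scenario`: a 20-tip backbone with a 50-tip Kingman
  clade (expected pairwise coalescence 0.001) grafted onto one tip, 200
  columns × 10 replicates. The backbone (fixed random topology, mean
  branch 1.0, mean pairwise distance ≈ 2) is deliberately deep so its
  tips are close to independent draws from each column's equilibrium:
  the scenario isolates the taxon-oversampling effect, and at 40
  selected columns per replicate a shallower backbone would let
  estimator noise dominate the per-replicate median comparison.
* `non_ultrametric_scenario`: a 20-tip ladder (internode 0.1, pendant
  0.01), tip depths spanning a ~20-fold range as in serially sampled
  virus data. GSC94 concentrates almost all weight on the deepest
  cherry here; novelty scores do not.

The coalescent clade uses a Kingman process scaled so the expected
pairwise coalescence time equals the requested mean (expected
within-clade path length twice that); the original tip label is retained
as one clade member and `n_extra` new tips are labelled `<tip>_k`.

What the generator does *not* emulate: indels (gaps arise only from user
data and are treated as missing), across-site rate variation, model
misspecification between simulation and inference, and tree-inference
error. Passing benchmarks therefore demonstrate the estimators' behaviour
under a correctly specified stationary model, not their robustness to
real-data violations of it.

## Numerical choices and degenerate inputs

* Messages are rescaled to unit maximum with an accumulated log-scale;
  the per-tip normalisation of the conditional distributions absorbs the
  constants. A column with zero likelihood raises `ImpossibleDataError`.
* Multifurcations are resolved left-first into binary nodes joined by
  zero-length branches at tree construction. Zero-length branches have
  `I = 1` and identity `P`, so scores are invariant under the resolution
  (tested both ways); unifurcations are suppressed, absorbing lengths.
* Zero-length pendant twins get identical weights by construction; no
  tie-breaking is needed anywhere.
* GSC94's proportional split is 0/0 on an all-zero subtree; the branch is
  then split equally, preserving the weight-sum = tree-length invariant.
  HH94 excludes missing rows from both `r` and `d` and from that
  sequence's averaging denominator; all-missing sequences get weight 0.
* Monte-Carlo routines consume a single seeded generator with a fixed
  internal batch size, so results depend only on the seed.
* Column indices are 0-based in the API, 1-based in CLI reports.

## Problem sizes

Exact weights are routine to a few thousand tips (the cubic cost is per
*column* only for the conditional variant); the test suite and
acceptance script run on 2–70-tip fixtures, with the oracle sweeps at
≤ 5 tips (exhaustive) and 10 tips (10⁵ simulation iterations), and the
benchmark at 200 columns × 10 replicates per scenario — sizes chosen so
the exhaustive oracles stay exact and the whole suite runs in minutes.

## Known limitations

* No conditional fast approximation; `w̄^D` is not defined here.
* No codon-model constructor (a codon-state custom `Q` works) and no
  gamma rate heterogeneity.
* The Bayesian layer is an approximation: it treats weighted counts as
  independent evidence rather than integrating over the phylogeny, and
  with a uniform prior it shrinks toward uniform frequencies — helpful at
  background columns, harmful under strong selection.
* `tip_distances` is quadratic and meant for small trees and tests.
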