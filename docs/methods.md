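# Methods

## The model

A population of *N* agents occupies the nodes of an undirected simple graph
(minimum degree 1; generated graphs have minimum degree 2 and are
connected).  Each agent carries an integer capital *C_i(t)*; all agents
start at a common *C_0*, and fitness is *W_i(t) = C_i(t) − C_0*.  Time is a
sequence of *T = plays_per_individual × N* rounds.  Each round draws one
subject uniformly at random (with replacement), who plays game A with
probability *p* and game B otherwise (or always one of the two in the
single-game modes).

**Game A** transfers exactly one unit between the subject *i* and a
uniformly drawn neighbor *j* — zero-sum by construction, so in A-only mode
Σ*C_i* is conserved exactly.  The five behavioral patterns fix the payer:

* *Matthew*: the subject wins (object pays) with probability equal to its
  population fitness rank, φ_i = |{k : W_k ≤ W_i}| / N.  The count includes
  the subject, so φ ∈ [1/N, 1], and φ = 1 when all capitals are equal.
  This rank form is a reconstruction: the original statement of the rule
  gives its symbols (the fitnesses of all *N* agents) and two boundary
  behaviors (certain win at uniform capital; winning probability increasing
  with relative wealth), which the rank rule realizes with no free
  parameters.  It is isolated behind `matthew_win_prob` so an alternative
  functional form can be swapped in without touching the engine.
* *Harmony*: the richer of the pair pays; on ties the object pays the
  subject.  Consequence (tested): the capital gap never widens, and a tie
  becomes a gap of exactly 2.
* *Cooperation*: the subject always donates.
* *PCRC*: fair coin when the subject is not richer than the object,
  donation otherwise.
* *Random*: fair coin between a fair competition and a donation; the
  subject ends up paying with probability 3/4.

**Game B** is single-player: branch 1 (win probability *p1*) applies when
*C_i* is at or below the arithmetic mean of the neighbors' capitals, branch
2 (*p2*) otherwise, with ±1 unit per play.  The branch comparison is done
in exact integer arithmetic (*C_i·deg ≤ ΣC_nbr*), so there is no floating
tie ambiguity; ties select branch 1.  From a uniform start every first
game-B play therefore lands in branch 1 — the asymmetry that drives the
ratchet.

## Classification

With replicate-mean fitnesses d^(B) and d^(A+B) (end-of-run values, no
time averaging):

* STRONG: d^(A+B) > 0 > d^(B)
* WEAK_POSITIVE: d^(A+B) > d^(B) > 0
* WEAK_NEGATIVE: 0 > d^(A+B) > d^(B)
* NONE otherwise; all boundary equalities map to NONE (regions are open).

No significance test is applied — classification uses plain replicate
means, matching the 30-replicate averaging of the reference protocol.

## Network families

* **Lattice**: periodic side×side torus, von Neumann neighborhood, every
  degree exactly 4.
* **Rewired random graph**: exactly *L* accepted rewirings of the lattice;
  each picks a uniform edge, keeps one uniformly chosen endpoint, and
  reconnects the free end to a uniform node.  Proposals creating
  self-loops, parallel edges, isolated nodes, or disconnection are rejected
  and redrawn (every agent must keep a neighbor for game A; the edge count
  is conserved for every L).
* **α-family**: each node's degree is drawn from a truncated Poisson law
  (probability α) or from a power law with exponential cutoff
  P(k) ∝ k^(−γ) e^(−k/κ) on [2, N−1] (probability 1−α); the sequence is
  realized as a configuration-model graph made simple and connected by
  degree-preserving double-edge swaps.  α = 1 is the Poisson (random-graph)
  endpoint, α = 0 the scale-free endpoint.

Both heavy-tail shape parameters are fixed by two calibration constraints:
the mean degree (default 4) and a small-degree mass of 70% on degrees
{2, 3}, the observable that characterizes the reference scale-free
construction.  The fitted law (γ ≈ 2.37, κ ≈ 53 at mean 4) then reproduces
the remaining reference fractions without further freedom: 50.9% of nodes
at degree 2 (reference 50.23%), 79.5% at degrees {2,3,4} (80%), 85.0% at
{2..5} (85.47%), and 93.9% below degree 10 (94.54%).  A pure power law
tuned to the mean alone overshoots the {2,3} mass at 73.9%, which is why
the cutoff form was chosen.  The truncated-Poisson rate is solved so the
conditional mean (k ≥ 2) equals the target mean.  If a sampled sequence
has odd sum, one uniformly chosen node's degree is incremented.

## Randomness and determinism

All run-level randomness comes from one Mersenne-Twister stream seeded per
run; the draw order is frozen (subject; game choice; neighbor; one pattern
or branch variate, drawn only when the rule is stochastic in the current
state).  The compiled numba kernel and the pure-Python reference engine
reproduce the identical stream, and the test suite asserts bit-equality of
whole trajectories across all pattern × mode combinations.  Replicate *r*
of a set uses seed *base + r*; generated network families draw a fresh
graph instance per replicate (the reference protocol does not state
whether networks were regenerated per replicate — regeneration was chosen
so replicate scatter includes generator variance).  Sweeps derive each
cell's seed from the (p1, p2) values, not the grid position, and share one
set of replicate networks across all cells and both game modes (common
random numbers); a sub-grid sweep therefore reproduces the matching cells
of a full sweep bit-exactly.

Win comparisons use `rand ≤ p` in game B and `rand < 0.5` / `rand < φ` in
game A — measure-equivalent choices fixed so that scripted-variate tests
are exact.

## Oracle

An exact dynamic program enumerates every round's choices with rational
arithmetic for instances up to N = 6 nodes and T = 6 rounds, giving
E[d] exactly; enumeration probabilities sum to 1 by construction and are
asserted.  The engine is checked against it at 10⁵ replicates (4 standard
errors) across patterns and modes, and against the closed form
E[d] = (game-B rounds / N)(2q − 1) when both branches share win
probability q.

## Default parameters and problem sizes

* `plays_per_individual = 100`, `p = 0.5`, `C_0 = 0` (fitness depends only
  on capital differences, so `C_0` is irrelevant — asserted by a test).
* Reference fitness values: 100×100 lattice, 20–100 replicates per point
  (100 where the reference value is within ~0.2 of zero and the standard
  error must be a few hundredths).
* Phase-diagram sweeps default to step 0.025 and 30 replicates at N = 900
  (the reference figure protocol); the packaged qualitative checks run a
  step-0.1 grid with 10 replicates at N = 900, and the sweep-module
  property tests use still smaller populations — sizes chosen to keep the
  full suite fast while leaving every comparison statistically decidable
  at 4 standard errors.
* Scale-free calibration: N = 10,000, mean degree 4, minimum degree 2.

## What the generators do and do not emulate

The synthetic networks reproduce the degree-distribution interpolation
(δ → Poisson → scale-free at fixed mean degree) that the study manipulates,
including the printed small-degree fractions of the scale-free endpoint.
They do not reproduce degree–degree correlations, clustering, or community
structure of real networks, nor the exact (unpublished) construction
algorithm of the original scale-free generator; conclusions from passing
tests are about degree heterogeneity, not about those higher-order
features.

## Known limitations and open reconstructions

* The Matthew win-probability is a reconstruction (see above); all
  Matthew-specific quantitative checks are therefore held to qualitative
  or loose-tolerance form.
* Two reference fitness values very close to zero are not reproduced:
  B-only on the lattice at (0.53, 0.47) measures +0.15 here against a
  reference −0.04, and at (0.13, 0.885) measures +0.37 against −0.04, with
  standard errors near 0.01–0.04.  The implemented rules reproduce the
  eight larger-magnitude lattice references to within ~0.1, and tested
  rule variants (strict inequality at the branch boundary;
  permutation-sweep scheduling) destroy those agreements, so the
  discrepancy is carried openly rather than absorbed by a rule change.
  One paradox label (PCRC at (0.13, 0.885)) flips as a consequence.
* On the lattice the strong-paradox band of the (p1, p2) plane is thin:
  high-replicate scans find no step-0.1 grid cell whose expected fitnesses
  classify STRONG, even though off-grid points inside the band do (the
  default sweep step of 0.025 exists precisely to resolve it).  Coarse-grid
  lattice sweeps therefore show an empty or sampling-noise-dependent strong
  region.  The band widens enough to register on a step-0.1 grid after
  heavy rewiring for the competition-leaning patterns (Matthew,
  cooperation, random) and on the scale-free family for all patterns, but
  stays sub-grid on the rewired family for harmony and PCRC.
* Analytic (Markov-chain or mean-field) treatments of the games are out of
  scope; the oracle is exhaustive enumeration, feasible only for toy
  instances.
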