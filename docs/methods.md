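# Methods

## The model

`netembed` implements a generative null model for coupling two network
layers: a large undirected, unweighted network A (think: a social
network, N_A nodes) is *embedded* into a small undirected, unweighted
location network B (N_B nodes, N_A > N_B; think: spatial adjacency of
counties or cities). Every B-node i carries an attractiveness f_i > 0,
normalized to Σ f_i = 1, interpreted as its probability of attracting
nodes from A.

The assignment rule repeats until every A-node has a location:

1. pick an unassigned *source* node of A uniformly at random and assign
   it to B-node i with probability f_i;
2. for each currently unassigned neighbor of the source in A, run an
   attractiveness-weighted random walk on B starting at i with per-step
   stopping probability q, and assign the neighbor to the node where the
   walk halts. The hop kernel is the column-stochastic matrix
   C_ij = f_i B_ij / Σ_l f_l B_lj.

The halt test is applied at the start node *before* the first hop
(stop-before-move), so a walk returns its start with probability at
least q. This convention is forced by the q = 1 limit, where every walk
must halt at the source's location and the embedding is maximally local.
The q → 0 limit is implemented without infinite walks: neighbors are
assigned directly from the stationary distribution v0 of C (eigenvalue-1
eigenvector, L1-normalized), the maximally delocalized embedding.
Neighbors assigned inside a step do not cascade — their own neighborhoods
are only expanded if they are later drawn as sources, which cannot happen
once assigned.

Outputs per realization: the assignment map, the realized populations
Φ_i (A-nodes per B-node), and the embedded weighted adjacency Γ, where
Γ_ij counts A-edges between the groups assigned to i and j and the
diagonal counts within-group edges once. Two conservation laws hold
exactly in every realization and are asserted in the tests:
Σ Φ_i = N_A and Σ_{i≤j} Γ_ij = |E_A|.

## Mean-field description

The analytics use only the degree moments of A (⟨k⟩_A, ⟨k²⟩_A) but the
full adjacency of B. The state of the assignment process at continuous
time t (one unit = one source selection) is reduced to four moments of
the unassigned pool: its size η, the first and second moments k1, k2 of
the number of *unassigned* neighbors of an unassigned node, and the mean
number kd of *assigned* neighbors.

One step removes a uniform source (unassigned-degree k ~ P) and its k
unassigned neighbors, which are reached along edges and therefore carry
the size-biased degree law k P(k)/k1. On a locally tree-like network
with no degree–degree correlations, the expected one-step changes of the
moment sums give, with D = η − 1 − k1:

    dk1/dt = [k1² + k1 − 2 k2] / D
    dk2/dt = [−k3 − 2 k2²/k1 + 3 k2 − k1 + k1 k2] / D
    dkd/dt = [k2 − k1] / D
    dη/dt  = −(1 + k1)

with initial conditions η(0) = N_A, k1(0) = ⟨k⟩_A, k2(0) = ⟨k²⟩_A,
kd(0) = 0. The second-moment equation involves the third raw moment k3,
closed with the Poisson-type skewness closure

    k3 = 3 k1 k2 − 2 k1³ + μ3,   μ3 = k2 − k1²,

i.e. third central moment equal to the variance — exact for a Poisson
law. The rationale: the unassigned-degree distribution of an ER network
starts Poisson, and the dominant operations on it (random removal,
size-biased removal, edge decrements) keep it approximately in the
Poisson family. Validation against direct simulation (500 traced
runs, fresh ER(1000, 0.01) A per run) shows the integrated trajectories
of k1, k2, kd tracking the ensemble means within ~2 standard errors over
the bulk of the process, and the completion time within ~1.5%.

The η closure (one source plus its expected k1 unassigned neighbors
leave the pool per step) is the unique smooth closure consistent with
the completion condition N_A = ∫₀^{t*} [1 + k1(t)] dt, which defines t*.

### Numerical integration

Classical fixed-step RK4 (default step 0.1 time units) from the exact
initial conditions. The denominators D = η − 1 − k1 vanish near
completion; integration stops when D would fall below a guard of
1e−6 · N_A, halving the step down to 1/256 of the nominal step near the
terminal point so that the guard crossing — and hence t* — is resolved
independently of the nominal step (halving the nominal step moves α, β
and t* by less than 1e−4 relative; a convergence utility exposes this
check). t* is then located from the completion condition: by linear
interpolation if η crosses zero on the grid, otherwise by extrapolating
the remaining pool with the last valid k1. Tiny violations of Jensen's
inequality k2 ≥ k1² from roundoff (below 1e−9) are clamped; larger ones
raise. In the terminal regime the continuum system may push k2 below k1,
which is impossible for an integer count distribution — another sign the
description is meaningless once the pool is nearly empty; all summary
integrals are dominated by the bulk.

### Integral summaries

All predictions depend on the trajectory only through integrals up to
t*:

    α    = ∫ k1 dt                 (nodes embedded through walks)
    β    = ∫ [k2 − k1 + k1 kd] dt  (stubs placed through the f-draw side)
    γ    = ∫ kd dt                 (stubs attached to walk-assigned nodes)
    δ(q) = ∫ [1 + q k1] dt = t* + q α

Two conservation identities pin these down exactly:

* node conservation makes α = N_A − t* an identity; the implementation
  evaluates α that way (t* carries the RK4 accuracy) and keeps the
  direct quadrature as the `alpha_quad` diagnostic (they agree to ~1e−6
  relative);
* stub conservation: every A-edge is either one of the α synchronous
  pairs (consuming two stubs through one walk) or contributes its two
  stubs to the β + γ pool, hence γ = N_A⟨k⟩_A − 2α − β. The
  implementation *defines* γ through this identity and keeps the direct
  quadrature ∫ kd dt as the `gamma_quad` diagnostic. The two agree only
  to the accuracy of the moment closure (~0.5% relative on ER
  networks); the identity-based value is the one that makes the
  predicted edge mass exact, which is why it is primary.

## Closed-form predictions

With Ω(q) = Σ_{r≥1} (1−q)^r C^r (computed by the dense linear solve
Ω = (1−q)C(I−(1−q)C)⁻¹, never by series truncation outside tests) the
expected populations are

    ⟨Φ_i⟩ = f_i δ(q) + q α Σ_j f_j Ω(q)_ij          0 < q < 1
    ⟨Φ_i⟩ = N_A f_i                                  q = 1
    ⟨Φ_i⟩ = f_i (N_A − α) + α v0_i                   q = 0

Each form sums to N_A exactly (δ(q) + (1−q)α = t* + α = N_A).

The expected embedded adjacency splits A-edges into *synchronous* pairs
(source and neighbor placed in the same step, correlated through one
walk) and *asynchronous* ones (paired at random through stub counts
φ_i):

    ⟨Γ_ij⟩ = ψ_ij + (φ_i φ_j / Σ_l φ_l)(1 − δ_ij/2)

with, for q ≠ 0 (ω_ij = f_j Ω(q)_ij):

    ψ_ij = q α f_i δ_ij + q α (ω_ij + ω_ji)(1 − δ_ij/2)
    φ_i  = (q β + γ) f_i + q β Σ_l f_l Ω(q)_il

and for q = 0:

    ψ_ij = α (f_i v0_j + f_j v0_i)(1 − δ_ij/2)
    φ_i  = γ f_i + β v0_i

Total masses are exact for every q: Σ_{i≤j} ψ_ij = α (the column sums of
Ω are (1−q)/q), Σ φ_i = β + γ, so Σ_{i≤j} ⟨Γ_ij⟩ = α + (β + γ)/2 =
N_A⟨k⟩_A/2 = |E_A|. At q = 1, Ω vanishes and the assembly collapses to

    ⟨Γ_ij⟩ = f_i α δ_ij + f_i f_j (N_A⟨k⟩_A − 2α)(1 − δ_ij/2),

which depends only on B's attractiveness and A's mean degree; the
implementation computes this shortcut and cross-checks it against the
general assembly to 1e−10 (exact because γ satisfies stub conservation
exactly). The self-loop share tr Γ / Σ_{i≤j} Γ_ij of the prediction is
nondecreasing in q — localization concentrates edge mass inside
locations.

## Synthetic data and what passing tests show

The built-in generators reproduce the reference experimental conditions:

* network A: ER G(n, p) with defaults N_A = 1000, p = 0.01, regenerated
  per realization; BA preferential attachment (m = 1 gives a tree) as
  the heavy-tailed alternative;
* network B: 50 points uniform on the unit square joined by Delaunay
  neighborship (the adjacency of the Voronoi tessellation, open
  boundaries — always connected and planar); a path graph serves as a
  degenerate stress case;
* attractiveness: i.i.d. Uniform(1, 100) rescaled to sum to one;
* ensembles of 1000 realizations by default (tests and the acceptance
  script scale this to 150–500 with per-realization seeds base+1+index).

These fixtures are tree-like, uncorrelated and unclustered, which is
exactly the regime the mean-field derivation assumes. Passing the
simulation-vs-theory suites therefore demonstrates internal consistency
of simulator and analytics under those assumptions; it does *not* show
the closed forms remain accurate for clustered or degree-correlated A.
On BA networks, whose degree correlations and heavy tail violate both
the uncorrelated assumption and the Poisson-type closure, the moment
system misestimates α substantially (observed ~40% at N_A = 300, m = 1);
conservation laws still hold exactly there, and only conservation is
claimed for BA in the test suite.

## Statistical comparisons

Ensemble comparisons use entrywise z = (sim mean − prediction)/SE with
SE over realizations (ddof = 1), excluding structural zeros (entries
where both simulation and prediction are exactly zero). The agreement
criterion is the fraction of entries with |z| < 3, thresholded at 95%.
Trajectory checkpoints are 10 evenly spaced steps from 0 to the time the
mean-field η reaches 0.1 · N_A: the continuum moment description assumes
a large pool, and deviations grow as it empties, so comparisons beyond
that point would measure the (documented) terminal breakdown rather than
the bulk fidelity.

## Design choices where the design was open

* Stop-before-move walk semantics (the r = 0 halt carries mass q):
  required by the q = 1 limit and by the structure of the population
  formula, whose walk term carries q(1−q)^r for r ≥ 1 plus the δ(q) term
  containing the r = 0 mass.
* Γ is accumulated from the final assignment map rather than
  incrementally; equivalent and simpler, and it makes the conservation
  law structural.
* Ω(q) via dense linear solve; B is small by the model's premise
  (N_A ≫ N_B). The truncated series survives only as a test oracle.
* The stationary distribution uses a dense eigensolver (eigenvalue
  closest to 1, positivity-fixed sign, L1 normalization) with a
  power-iteration fallback on (I + C)/2 for degenerate returns;
  disconnected B is rejected with its components reported rather than
  handled per-component. Bipartite B is accepted — only the stationary
  vector is used, never chain convergence.
* Voronoi adjacency = Delaunay neighborship with open boundaries (no
  periodic wrapping); degenerate point sets are re-sampled with a log
  message.
* When A comes from a generator the pipeline regenerates it for every
  realization and integrates the mean-field once with the ensemble-mean
  degree moments; with a file-backed A all realizations share the graph
  and the report labels the regime.
* Attractiveness accepts arbitrary positive weights and normalizes
  internally, so raw capacities (city populations) can be passed as-is.
* α, β, γ, δ(q) always come from one integration; predictions take one
  `IntegralSummaries` object, so summaries from different trajectories
  cannot be mixed.

## Known limitations

* The moment system's third-moment closure is Poisson-type; accuracy
  degrades on broad or correlated degree distributions (BA) and for
  high-clustering A.
* γ from stub conservation and from quadrature of kd differ by the
  closure error (~0.5% on ER); the package reports both.
* Predictions are means only; no variance or distributional predictions
  for Φ or Γ.
* The continuum description is not meaningful once the unassigned pool
  is nearly empty; t* is resolved by interpolation/extrapolation of the
  completion integral, not by chasing the terminal singularity.
* No dynamical processes on the embedded network, no partial embeddings,
  no degree-biased source selection.
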