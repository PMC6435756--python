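# Methods

## Model and objectives

`leidenkit` clusters an undirected weighted graph by greedily optimising a
partition quality function.  Two objectives are implemented, both with a
resolution parameter γ > 0.

**Modularity.**  `H = (1/2m) Σ_c (2 E_c − γ K_c²/(2m))`, where `E_c` is the
internal edge weight of community *c* with each unordered pair counted once
(so `2 E_c` is the internal *end* count), `K_c` the summed strengths and `m`
the total edge weight.  With this convention the all-in-one partition
scores exactly 0 at γ = 1 — the canonical definition.  The internal edge
term of the objective is sometimes written with the ends counted singly;
we use the doubled form precisely so the canonical normalisation holds.

**CPM.**  `H = Σ_c (E_c − γ n_c(n_c−1)/2)`, with `n_c` the *summed node
size* of the community.  Node sizes are 1 on a raw network; after
aggregation they are the summed sizes of the collapsed nodes, which makes
the pair count — and hence CPM — exactly invariant under aggregation.  γ
acts as a density threshold: a set of nodes is worth keeping together only
if it is internally denser than γ.

**Self-loops.**  A self-loop of weight *w* contributes 2*w* to its node's
strength, *w* to `E_c` and *w* to `m`.  This is the unique convention under
which collapsing a community into a single self-looped node preserves both
objectives exactly; the multi-level recursion of both algorithms depends
on it, and the test suite asserts preservation to 1e−9 on randomized
instances.

## Algorithms

**Louvain baseline.**  Local moving (sweep all nodes in random order,
greedily move each to the best community including a fresh empty one,
repeat until a full sweep moves nothing) alternating with aggregation,
recursing until the aggregate level stops changing.  Moves to an empty
community are always candidates — required for CPM optima.  Ties among
equally good targets keep the current community, else take the lowest
label, so runs are reproducible per seed.

**Leiden.**  Each iteration runs three phases per level:

1. *Fast local move.*  A queue starts with all nodes in random order; a
   popped node takes its best strictly improving move and its neighbours
   outside its new community re-enter the queue.  The queue never holds
   duplicates.  Because a move also shifts the aggregate terms (`K_c`,
   `n_c`) seen by nodes that are *not* neighbours of the mover, the queue
   discipline alone does not quite reach a local optimum; after the queue
   drains, a verification sweep re-seeds it with any node that can still
   improve.  The node-optimality postcondition therefore holds exactly,
   at the cost of one O(m) sweep per drain.

2. *Refinement.*  Starting from singletons, nodes are merged only within
   each community *S* of the local-move partition 𝒫.  A node (or a target
   subcommunity *C*) takes part only if it is well connected inside *S*:
   its cut to the rest of *S* must reach the γ-density bound
   `γ·n_v(n_S−n_v)` for CPM, or the strength-product analogue
   `γ·k_v(K_S−k_v)/(2m)` for modularity (the same rescaling modularity
   applies to CPM's penalty).  These bounds are exactly the condition under
   which node optimality of 𝒫 certifies every node as well connected, so
   refinement never stalls on a freshly optimised partition.  A node still
   in a singleton community picks among the quality-non-decreasing merge
   targets at random with probability ∝ exp(ΔH/θ); decreasing mergers are
   never taken.  θ → 0 recovers the greedy choice (asserted against an
   independent greedy reference over 1000 seeded draws); larger θ spreads
   the choice.  Default θ = 0.01, sane range roughly [0.0005, 0.1].

3. *Aggregation.*  The aggregate network is built on the *refined*
   partition; the initial partition of the aggregate level groups the
   refined pieces by their community in 𝒫.  The recursion ends when each
   community is a single aggregate node and local moving finds nothing —
   at that point node optimality of the top level is exactly γ-separation
   of the output.  If a refinement pass happens to merge nothing (possible
   only through ties in the selection kernel), it is simply redrawn, with
   a small cap on redraws to guarantee termination.

Because a subcommunity only ever absorbs nodes connected to it with
positive weight, every refined community — and hence every output
community — induces a connected subgraph.  This is the central guarantee
the plain Louvain algorithm lacks.

**Iterated runs.**  Both algorithms are run iteratively, each iteration
seeded with the previous partition.  `stop_policy` is `fixed_iterations`,
`until_stable` (stop at the first unchanged iteration) or
`until_converged`.  For Louvain, every iteration after a stable one is
provably stable, so `until_stable` is exact.  For Leiden the randomized
refinement means a stable iteration can be followed by an improving one
(the test suite exhibits this by seed search), so `until_converged`
demands two consecutive unchanged iterations and re-checks node optimality
and γ-separation before stopping.  This is a finite proxy for an
asymptotic property: subset optimality at convergence is guaranteed only
in the limit of infinitely many iterations, and the converged partition
can — rarely, order-dependently — still admit a profitable multi-node
subset move that refinement had not yet stumbled upon.  The checkers
measure this honestly rather than hiding it; on small-graph harnesses the
converged outputs are subset optimal in roughly 98–100% of communities.

## Guarantee checkers and audit

γ-separation scans adjacent community pairs with the exact merge delta
(non-adjacent merges are always losses).  Node optimality scans every
node's best move.  Subpartition γ-density, uniform γ-density and subset
optimality are exhaustive (2^k bipartitions / subsets) and capped at
communities of 12 nodes; beyond the cap they return "not checkable",
which is distinct from failure.  The subset-move delta used by the
exhaustive checkers is computed by full quality recomputation, deliberately
independent of the incremental delta formulas it cross-checks.

The audit re-clusters each community's induced subnetwork with Leiden run
until a stable iteration.  For modularity the subnetwork keeps the full
graph's `2m` and its members' original strengths as the null model, so
that a split found on the subnetwork is guaranteed to raise the global
objective (CPM needs no adjustment; its terms are local).  A split
community is *badly connected*; a disconnected one is the extreme case and
counts as badly connected too.  The audit is a lower bound — communities
it does not split are not certified well connected.

## Synthetic data

**Planted partition.**  `n` nodes in equal communities of
`community_size` (default 50); exactly `round(n·⟨k⟩/2)` distinct edges
(default ⟨k⟩ = 10); each edge is inter-community with probability μ, else
intra-community, with endpoints uniform within the chosen communities.
The inter/intra label is drawn before the endpoints, so the inter-edge
count is exactly Binomial(m, μ); collisions are resampled within their
category, keeping the mixture unbiased (the realized mean degree is exact
by construction).  For CPM runs, γ is set to the midpoint of the expected
within-community density `p_in = (1−μ)⟨k⟩/(c−1)` and between-community
density `p_out = μ⟨k⟩/(n−c)` — the natural operating point for a density
threshold; a flag warns when `p_in ≤ p_out` (undetectable by density).

What this emulates — and does not.  The generator produces equal-size
communities and Poisson-like degrees; real networks have heavy-tailed
degrees and community sizes, degree-community correlations and overlapping
structure.  Passing recovery tests here shows the optimiser finds planted
density structure at a sensible γ; it does not certify performance on
heavy-tailed empirical networks.  One consequence is worth stating
plainly: with mean intra-degree `(1−μ)⟨k⟩`, a few nodes per thousand draw
so few within-community edges that, at the midpoint γ, the objective
*genuinely prefers* them outside their planted community — the γ-optimum
is then not the planted partition, and an optimiser that is working
correctly recovers it only up to those stragglers (ARI/NMI ≈ 0.87/0.93 at
μ = 0.2 rather than exact equality).  We verified this is a property of
the objective, not of our search, by cross-checking against an independent
Leiden implementation, which finds the same higher-scoring split
partitions.

**Bridge fixture.**  A hub node bridges two strongly tied triads and is
also connected to an external clique.  Weights (triad ties 10, bridges 1,
hub-clique pulls 2) are certified at construction by explicit delta
checks: the hub's departure is strictly improving, afterwards no triad
node has an improving single move, the stranded community has exactly two
components, and the post-move partition is γ-separated.  Louvain therefore
ends with a disconnected community from this start for every seed, while
Leiden splits the triads into two connected communities with strictly
higher modularity.

## Numerical choices

* Improvement threshold: a move counts as improving only if its delta
  exceeds 1e−12 (absolute), preventing rounding-noise move loops.
* Refinement candidates admit ΔH ≥ −1e−12, so exact-zero merges stay
  reachable; the sampling logits are max-shifted before exponentiation to
  avoid overflow at small θ.
* All randomness — visit orders, refinement draws — flows from one
  `numpy.random.Generator` per run, seeded from the config; runs are
  bit-reproducible per seed.
* Degenerate inputs: an edgeless graph is valid for CPM (singleton
  optimum) and rejected for modularity (m = 0); empty node sets,
  non-positive weights and malformed files raise typed errors naming the
  offending line.

## Problem sizes used in the shipped harnesses

The test and acceptance harnesses run the full pipeline at desk scale:
planted benchmarks at n = 1000 (10 seeds), connectivity sweeps over
random graphs up to n = 300, exhaustive checkers on communities of at
most 12 nodes, and 1000-case delta-oracle comparisons.  These sizes make
every claim checkable in seconds while exercising all code paths; the
algorithms themselves have no size-specific logic.

## Known limitations

* Undirected graphs only; no directed, bipartite or streaming variants.
* Exhaustive certification of subset optimality is exponential and
  therefore only available for small communities; no polynomial
  certificate is known.
* The audit certifies badly-connectedness, never well-connectedness.
* `until_converged` is a stopping heuristic for an asymptotic guarantee,
  as discussed above.
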