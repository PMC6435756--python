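"""Leiden algorithm: fast local move, randomized refinement, guided aggregation.

Each iteration has three phases:

1. **Fast local move** — queue-based local moving.  The queue starts with
   all nodes in random order; when a node moves, only its neighbours
   outside its new community re-enter the queue, so nodes whose
   neighbourhood is unchanged are never revisited.

2. **Refinement** — starting from singletons, nodes are merged *within*
   each community ``S`` of the local-move partition 𝒫.  Only nodes and
   subcommunities that are well connected inside ``S`` (their cut to the
   rest of ``S`` meets the γ-density bound) take part.  A node still in a
   singleton community picks its target among the non-decreasing merges at
   random, with probability ∝ exp(ΔH/θ); quality-decreasing mergers are
   never taken.  θ → 0 recovers the greedy choice; the default θ = 0.01
   allows some, but not too much, randomness.

3. **Aggregation** — the aggregate network is built on the *refined*
   partition, while the initial partition for the aggregate level groups
   the refined communities by their community in 𝒫.

The recursion ends when every community is a single aggregate node and
local moving makes no further move.  Because a subcommunity only ever
absorbs nodes positively connected to it, every community the algorithm
returns induces a connected subgraph — the central connectivity guarantee
that plain Louvain lacks.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition, aggregate
from .quality import CPM, EPS, QualitySpec, delta_move

__all__ = [
    "LeidenConfig",
    "fast_local_move",
    "merge_nodes_subset",
    "refine_partition",
    "leiden_iteration",
]

FIXED_ITERATIONS = "fixed_iterations"
UNTIL_STABLE = "until_stable"
UNTIL_CONVERGED = "until_converged"


@dataclass(frozen=True)
class LeidenConfig:
    """Run configuration.

    theta : randomness of refinement target selection (> 0); sane range is
        roughly [0.0005, 0.1].
    seed : RNG seed; every randomized order and draw comes from one
        generator seeded with it.
    max_iterations : cap on outer iterations.
    stop_policy : ``fixed_iterations`` runs exactly ``max_iterations``;
        ``until_stable`` stops at the first iteration that leaves the
        partition unchanged; ``until_converged`` additionally requires two
        consecutive unchanged iterations (randomized refinement means a
        stable iteration can still be followed by an improving one).
    """

    theta: float = 0.01
    seed: int = 0
    max_iterations: int = 10
    stop_policy: str = UNTIL_STABLE

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stop_policy not in (FIXED_ITERATIONS, UNTIL_STABLE,
                                    UNTIL_CONVERGED):
            raise ValueError(f"unknown stop policy {self.stop_policy!r}")


def fast_local_move(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    rng: np.random.Generator,
) -> Partition:
    """Queue-based local moving; returns a node-optimal partition.

    Visits each node once in random order, then revisits only nodes whose
    neighbourhood changed (neighbours of a moved node outside its new
    community).  The queue never holds duplicates.
    """
    from .louvain import best_move

    p = partition.copy()
    order = rng.permutation(graph.n)
    queue = deque(int(v) for v in order)
    in_queue = np.ones(graph.n, dtype=bool)
    while queue:
        while queue:
            v = queue.popleft()
            in_queue[v] = False
            target, d = best_move(graph, p, v, spec)
            if d > EPS:
                p.move(v, target)
                new_c = p.community_of(v)
                for u, _ in graph.adj[v]:
                    if p.community_of(u) != new_c and not in_queue[u]:
                        queue.append(u)
                        in_queue[u] = True
        # a move also shifts the aggregate terms (K_c, n_c) seen by nodes
        # that are *not* neighbours of the mover, which the neighbourhood
        # queue cannot track; one verification sweep re-seeds the queue
        # with any node that can still improve, so the node-optimality
        # contract holds exactly
        for v in rng.permutation(graph.n):
            v = int(v)
            _, d = best_move(graph, p, v, spec)
            if d > EPS and not in_queue[v]:
                queue.append(v)
                in_queue[v] = True
    return p


def _well_connected_bound(
    graph: Graph, spec: QualitySpec, size: float, total: float
) -> float:
    """γ-density cut bound for a part of given size within a set of given
    total size.  For CPM sizes are node sizes; for modularity they are
    strengths and γ is rescaled by the configuration-model factor 1/2m."""
    if spec.objective == CPM:
        return spec.gamma * size * (total - size)
    return spec.gamma * size * (total - size) / (2.0 * graph.null_m)


def merge_nodes_subset(
    graph: Graph,
    refined: Partition,
    subset: np.ndarray,
    spec: QualitySpec,
    theta: float,
    rng: np.random.Generator,
) -> Partition:
    """Randomized within-community merging for one community ``subset`` of 𝒫.

    Mutates and returns ``refined``.  Nodes of ``subset`` must currently be
    singletons in ``refined``.  A node participates only if it is well
    connected within the subset, may merge only into a refined community
    that is itself well connected within the subset, and the target is
    sampled among the non-decreasing options with probability
    ∝ exp(ΔH/θ) (staying put, ΔH = 0, is always an option).
    """
    S = [int(v) for v in subset]
    if len(S) <= 1:
        return refined
    in_S = set(S)
    if spec.objective == CPM:
        node_size = {v: float(graph.node_sizes[v]) for v in S}
    else:
        node_size = {v: float(graph.null_strengths[v]) for v in S}
    total = sum(node_size.values())

    # cut of each node to the rest of S
    ext = {v: sum(w for u, w in graph.adj[v] if u in in_S) for v in S}
    # per refined community within S: cut to rest of S and size
    comm_cut = {refined.community_of(v): ext[v] for v in S}
    comm_size = {refined.community_of(v): node_size[v] for v in S}

    for v in rng.permutation(np.array(S, dtype=np.int64)):
        v = int(v)
        cv = refined.community_of(v)
        if refined.counts[cv] != 1:
            continue  # only nodes still in a singleton community may merge
        if ext[v] < _well_connected_bound(graph, spec, node_size[v], total):
            continue
        # candidate refined communities inside S, well connected themselves
        w_comm: dict[int, float] = {}
        for u, w in graph.adj[v]:
            if u in in_S:
                c = refined.community_of(u)
                if c != cv:
                    w_comm[c] = w_comm.get(c, 0.0) + w
        candidates = [cv]
        deltas = [0.0]
        for c, w_vc in sorted(w_comm.items()):
            if comm_cut[c] < _well_connected_bound(
                graph, spec, comm_size[c], total
            ):
                continue
            d = delta_move(graph, refined, v, c, spec,
                           w_old=0.0, w_new=w_vc)
            if d >= -EPS:
                candidates.append(c)
                deltas.append(d)
        if len(candidates) == 1:
            continue
        darr = np.array(deltas)
        logits = (darr - darr.max()) / theta
        probs = np.exp(logits)
        probs /= probs.sum()
        choice = int(rng.choice(len(candidates), p=probs))
        target = candidates[choice]
        if target == cv:
            continue
        w_vt = w_comm[target]
        refined.move(v, target, compact=False)
        # v's old singleton community disappears; update target bookkeeping
        old_cut = comm_cut.pop(cv, ext[v])
        old_size = comm_size.pop(cv, node_size[v])
        tgt_cut = comm_cut.get(target, 0.0)
        tgt_size = comm_size.get(target, 0.0)
        comm_cut[target] = tgt_cut + old_cut - 2.0 * w_vt
        comm_size[target] = tgt_size + old_size
    return refined


def refine_partition(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    theta: float,
    rng: np.random.Generator,
) -> Partition:
    """Refine 𝒫: start from singletons, merge within each community of 𝒫.

    Every community of the result is a subset of a community of
    ``partition``, and induces a connected subgraph.
    """
    refined = Partition.singleton(graph)
    for c in range(partition.n_communities):
        merge_nodes_subset(graph, refined, partition.members(c), spec,
                           theta, rng)
    # drop empty labels left by label-stable moves
    return Partition(graph, refined.membership)


def leiden_iteration(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    config: LeidenConfig,
    rng: np.random.Generator,
) -> Partition:
    """One full Leiden iteration, lifted back to the original nodes.

    Every community of the output induces a connected subgraph and the
    output is γ-separated (no pair of communities merges profitably).
    """
    maps: list[np.ndarray] = []
    g, p = graph, partition.copy()
    no_merge_redraws = 0
    while True:
        p = fast_local_move(g, p, spec, rng)
        if p.n_communities == g.n:
            break
        refined = refine_partition(g, p, spec, config.theta, rng)
        if refined.n_communities == g.n:
            # refinement merged nothing, so aggregation would not shrink the
            # network.  After local moving every node is well connected
            # within its community (node optimality is exactly the γ-cut
            # bound), so a non-trivial refinement exists and a redraw almost
            # surely finds one; the cap guards degenerate all-tie cases.
            no_merge_redraws += 1
            if no_merge_redraws >= 8:
                break
            continue
        no_merge_redraws = 0
        g, _ = aggregate(g, refined)
        maps.append(refined.membership.copy())
        # aggregate node = refined community; its initial community is the
        # community its members had in the non-refined partition
        init = np.empty(g.n, dtype=np.int64)
        for c in range(refined.n_communities):
            init[c] = p.membership[refined.members(c)[0]]
        p = Partition(g, init)
    memb = p.membership
    for level_map in reversed(maps):
        memb = memb[level_map]
    return Partition(graph, memb)
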