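"""Louvain algorithm: greedy local moving plus aggregation, iterated.

Serves two roles: the comparison baseline, and the generator of the
badly-connected pathology the refinement-based algorithm is designed to
fix.  Local moving repeatedly sweeps all nodes in random order, moving
each to the community (an existing neighbour community or a fresh empty
one) with the largest quality gain, until a full sweep moves nothing.
Aggregation collapses communities to nodes and the two phases recurse on
the aggregate network; the result is lifted back to the original nodes.

Ties among equally-best targets are broken by keeping the current
community if it ties the best, else by lowest community label, so runs
are bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np

from .graph import Graph, Partition, aggregate
from .quality import EPS, QualitySpec, delta_move

__all__ = ["louvain_move_nodes", "louvain_iteration", "best_move"]


def best_move(
    graph: Graph, partition: Partition, v: int, spec: QualitySpec
) -> tuple[int, float]:
    """Best single-node move for ``v``: ``(target, delta)``.

    Candidates are the communities of ``v``'s neighbours plus a fresh empty
    community.  Returns the current community with delta 0.0 when no move
    strictly improves (ties favour staying; otherwise the lowest label).
    """
    old = partition.community_of(v)
    w_comm: dict[int, float] = {old: 0.0}
    for u, w in graph.adj[v]:
        c = partition.community_of(u)
        w_comm[c] = w_comm.get(c, 0.0) + w
    w_old = w_comm[old]
    fresh = partition.n_communities
    w_comm.setdefault(fresh, 0.0)
    best_c, best_d = old, 0.0
    for c in sorted(w_comm):
        if c == old:
            continue
        d = delta_move(graph, partition, v, c, spec,
                       w_old=w_old, w_new=w_comm[c])
        if d > best_d + EPS:
            best_c, best_d = c, d
    return best_c, best_d


def louvain_move_nodes(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    rng: np.random.Generator,
) -> Partition:
    """Greedy local moving until a full random-order sweep moves no node.

    The returned partition is node optimal: no single-node move (including
    to a fresh community) has a positive quality delta.
    """
    p = partition.copy()
    moved = True
    while moved:
        moved = False
        order = rng.permutation(graph.n)
        for v in order:
            v = int(v)
            target, d = best_move(graph, p, v, spec)
            if d > EPS:
                p.move(v, target)
                moved = True
    return p


def louvain_iteration(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    rng: np.random.Generator,
) -> Partition:
    """One full Louvain iteration: alternate local moving and aggregation
    until the aggregate level stops changing; lift back to original nodes."""
    # maps[i]: node at level i -> aggregate node at level i+1
    maps: list[np.ndarray] = []
    g, p = graph, partition.copy()
    while True:
        p = louvain_move_nodes(g, p, spec, rng)
        if p.n_communities == g.n:
            break
        g, _ = aggregate(g, p)
        maps.append(p.membership.copy())
        p = Partition.singleton(g)
    memb = p.membership
    for level_map in reversed(maps):
        memb = memb[level_map]
    return Partition(graph, memb)
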