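"""Checkers for the guarantee hierarchy, and the partition audit.

The properties, from weakest to strongest:

====================  ======================================================
γ-separation          no two communities can be merged with a quality gain
γ-connectivity        every community induces a connected subgraph (checked
                      here as plain connectivity)
node optimality       no single node can be moved with a quality gain
subpartition γ-dense  recursively: a community splits into two parts that
                      are well connected to each other, neither separable
                      from the community, each itself subpartition γ-dense
uniform γ-density     every bipartition of a community has cut weight at
                      least the γ-density bound
subset optimality     no subset of a community can be moved to another
                      community (or split off) with a quality gain; implies
                      all of the above
====================  ======================================================

Louvain guarantees γ-separation per iteration and node optimality after a
stable iteration; Leiden adds connectivity per iteration, subpartition
γ-density after a stable iteration, and uniform γ-density plus subset
optimality at convergence.

The exhaustive checkers enumerate bipartitions/subsets and are capped at
``max_exhaustive`` (default 12) nodes per community; larger communities
yield ``None`` ("not checkable"), distinct from ``False``.

The audit re-clusters each community's own subnetwork with Leiden under a
quality function *consistent* with the whole network (for modularity: the
full graph's 2m and original strengths are retained).  A community the
audit splits is *badly connected* — splitting it is then guaranteed to
increase the global objective.  Disconnected communities are the extreme
case and are counted among the badly connected.  The audit is a lower
bound: communities it does not split are not certified well connected.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, Partition, connected_components, induced_subgraph
from .quality import CPM, EPS, QualitySpec, delta_merge, quality

__all__ = [
    "AuditReport",
    "is_gamma_separated",
    "is_connected_partition",
    "is_node_optimal",
    "is_subpartition_gamma_dense",
    "is_uniformly_gamma_dense",
    "is_subset_optimal",
    "delta_subset_move",
    "audit_partition",
]

MAX_EXHAUSTIVE = 12


def is_gamma_separated(
    graph: Graph, partition: Partition, spec: QualitySpec, tol: float = EPS
) -> bool:
    """True iff no pair of communities can be merged with a quality gain.

    Only adjacent pairs need checking: merging two communities with no
    connecting edge changes quality by a strictly negative penalty term.
    """
    memb = partition.membership
    between: dict[tuple[int, int], float] = {}
    for (u, v), w in graph.edges.items():
        cu, cv = int(memb[u]), int(memb[v])
        if cu != cv:
            key = (cu, cv) if cu < cv else (cv, cu)
            between[key] = between.get(key, 0.0) + w
    for (c1, c2), w in between.items():
        if delta_merge(graph, partition, c1, c2, spec, between=w) > tol:
            return False
    return True


def is_connected_partition(graph: Graph, partition: Partition) -> bool:
    """True iff every community induces a connected subgraph."""
    for members in partition.communities():
        if len(members) <= 1:
            continue
        sub, _ = induced_subgraph(graph, members)
        if len(connected_components(sub)) > 1:
            return False
    return True


def is_node_optimal(
    graph: Graph, partition: Partition, spec: QualitySpec, tol: float = EPS
) -> bool:
    """True iff no single-node move (incl. to a fresh community) gains."""
    from .louvain import best_move

    for v in range(graph.n):
        _, d = best_move(graph, partition, v, spec)
        if d > tol:
            return False
    return True


def delta_subset_move(
    graph: Graph,
    partition: Partition,
    subset,
    target: int | None,
    spec: QualitySpec,
) -> float:
    """Quality change of moving a whole ``subset`` of one community to
    ``target`` (``None`` = a fresh community), by full recomputation.

    Deliberately independent of the incremental delta formulas: this is
    the reference path the exhaustive checkers rely on.
    """
    subset = [int(v) for v in subset]
    memb = partition.membership.copy()
    new_label = partition.n_communities if target is None else target
    memb[subset] = new_label
    return (quality(graph, Partition(graph, memb), spec)
            - quality(graph, partition, spec))


def _cut_and_bound(
    graph: Graph, spec: QualitySpec, part_a, part_b
) -> tuple[float, float]:
    """Cut weight between two node sets and the γ-density bound for it."""
    a = set(int(v) for v in part_a)
    b = set(int(v) for v in part_b)
    cut = sum(w for (u, v), w in graph.edges.items()
              if (u in a and v in b) or (u in b and v in a))
    if spec.objective == CPM:
        size_a = float(graph.node_sizes[sorted(a)].sum())
        size_b = float(graph.node_sizes[sorted(b)].sum())
        bound = spec.gamma * size_a * size_b
    else:
        k_a = float(graph.null_strengths[sorted(a)].sum())
        k_b = float(graph.null_strengths[sorted(b)].sum())
        bound = spec.gamma * k_a * k_b / (2.0 * graph.null_m)
    return cut, bound


def _bipartitions(members: list[int]):
    """All unordered bipartitions of ``members`` into two nonempty parts."""
    n = len(members)
    for mask in range(1, 2 ** (n - 1)):
        part_a = [members[i] for i in range(n) if mask >> i & 1]
        part_b = [members[i] for i in range(n) if not (mask >> i & 1)]
        yield part_a, part_b


def is_subpartition_gamma_dense(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    community: int,
    max_exhaustive: int = MAX_EXHAUSTIVE,
) -> bool | None:
    """Recursive brute-force subpartition γ-density check for one community.

    A node set is subpartition γ-dense if it is a singleton, or some
    bipartition (A, B) of it satisfies: (1) A and B are well connected to
    each other (cut ≥ γ-density bound); (2) neither part can be separated
    from its community (splitting it off does not raise quality); and
    (3) A and B are each subpartition γ-dense.  Returns ``None`` when the
    community exceeds ``max_exhaustive`` nodes.
    """
    members = [int(v) for v in partition.members(community)]
    if len(members) > max_exhaustive:
        return None

    def dense(nodes: list[int]) -> bool:
        if len(nodes) == 1:
            return True
        for part_a, part_b in _bipartitions(nodes):
            cut, bound = _cut_and_bound(graph, spec, part_a, part_b)
            if cut < bound - EPS:
                continue
            if delta_subset_move(graph, partition, part_a, None, spec) > EPS:
                continue
            if delta_subset_move(graph, partition, part_b, None, spec) > EPS:
                continue
            if dense(part_a) and dense(part_b):
                return True
        return False

    return dense(members)


def is_uniformly_gamma_dense(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    community: int,
    max_exhaustive: int = MAX_EXHAUSTIVE,
) -> bool | None:
    """Every bipartition of the community meets the γ-density cut bound."""
    members = [int(v) for v in partition.members(community)]
    if len(members) > max_exhaustive:
        return None
    if len(members) == 1:
        return True
    for part_a, part_b in _bipartitions(members):
        cut, bound = _cut_and_bound(graph, spec, part_a, part_b)
        if cut < bound - EPS:
            return False
    return True


def is_subset_optimal(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    community: int,
    max_exhaustive: int = MAX_EXHAUSTIVE,
    tol: float = EPS,
) -> bool | None:
    """No nonempty subset of the community can profitably move anywhere.

    Checks every nonempty subset against every other community and a fresh
    community.  The strongest guarantee; implies uniform γ-density.
    """
    members = [int(v) for v in partition.members(community)]
    if len(members) > max_exhaustive:
        return None
    targets = [c for c in range(partition.n_communities) if c != community]
    for r in range(1, len(members) + 1):
        for subset in itertools.combinations(members, r):
            if delta_subset_move(graph, partition, subset, None, spec) > tol:
                return False
            for t in targets:
                if delta_subset_move(graph, partition, subset, t, spec) > tol:
                    return False
    return True


@dataclass
class CommunityAudit:
    community: int
    n_nodes: int
    connected: bool
    badly_connected: bool
    n_subcommunities_found: int
    quality_gain: float


@dataclass
class AuditReport:
    """Per-community connectivity/badly-connected flags plus summary
    percentages (disconnected communities count as badly connected)."""

    objective: str
    gamma: float
    communities: list[CommunityAudit] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def pct_disconnected(self) -> float:
        if not self.communities:
            return 0.0
        bad = sum(not c.connected for c in self.communities)
        return 100.0 * bad / len(self.communities)

    @property
    def pct_badly_connected(self) -> float:
        if not self.communities:
            return 0.0
        bad = sum(c.badly_connected for c in self.communities)
        return 100.0 * bad / len(self.communities)

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "gamma": self.gamma,
            "n_communities": self.n_communities,
            "pct_disconnected": self.pct_disconnected,
            "pct_badly_connected": self.pct_badly_connected,
            "communities": [
                {"community": c.community, "n_nodes": c.n_nodes,
                 "connected": c.connected,
                 "badly_connected": c.badly_connected,
                 "n_subcommunities_found": c.n_subcommunities_found,
                 "quality_gain": c.quality_gain}
                for c in self.communities
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        lines = [
            f"{'community':>9}  {'nodes':>6}  {'connected':>9}  "
            f"{'badly_conn':>10}  {'subcomms':>8}  {'gain':>12}"
        ]
        for c in self.communities:
            lines.append(
                f"{c.community:>9}  {c.n_nodes:>6}  "
                f"{str(c.connected):>9}  {str(c.badly_connected):>10}  "
                f"{c.n_subcommunities_found:>8}  {c.quality_gain:>12.6g}"
            )
        lines.append(
            f"summary: {self.n_communities} communities, "
            f"{self.pct_disconnected:.1f}% disconnected, "
            f"{self.pct_badly_connected:.1f}% badly connected"
        )
        return "\n".join(lines)


def audit_partition(
    graph: Graph,
    partition: Partition,
    spec: QualitySpec,
    config=None,
) -> AuditReport:
    """Classify each community as connected / badly connected.

    For each community, its induced subnetwork is re-clustered with Leiden
    (run until a stable iteration) under a quality function consistent with
    the whole network: for modularity the subnetwork retains the full
    graph's 2m and the members' original strengths.  If the subnetwork
    splits into more than one community, the community is badly connected
    and the recorded ``quality_gain`` — the consistent-quality increase the
    split realises — is strictly positive.
    """
    from .leiden import UNTIL_STABLE, LeidenConfig
    from .runner import iterate

    if config is None:
        config = LeidenConfig(stop_policy=UNTIL_STABLE, max_iterations=20)
    report = AuditReport(objective=spec.objective, gamma=spec.gamma)
    for c in range(partition.n_communities):
        members = partition.members(c)
        sub, _ = induced_subgraph(graph, members, keep_null=True)
        connected = len(connected_components(sub)) == 1
        if sub.n == 1:
            report.communities.append(CommunityAudit(
                community=c, n_nodes=1, connected=True,
                badly_connected=False, n_subcommunities_found=1,
                quality_gain=0.0))
            continue
        sub_cfg = LeidenConfig(theta=config.theta, seed=config.seed + c,
                               max_iterations=config.max_iterations,
                               stop_policy=UNTIL_STABLE)
        rec = iterate(sub, spec, "leiden", sub_cfg)
        found = rec.final_partition
        n_sub = found.n_communities
        badly = n_sub > 1 or not connected
        gain = 0.0
        if n_sub > 1:
            gain = (quality(sub, found, spec)
                    - quality(sub, Partition.all_in_one(sub), spec))
        report.communities.append(CommunityAudit(
            community=c, n_nodes=int(len(members)), connected=connected,
            badly_connected=badly, n_subcommunities_found=n_sub,
            quality_gain=gain))
    return report
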