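"""Undirected weighted graphs, partitions, edge-list I/O and aggregation.

The graph model is the one community-detection quality functions operate on:
an undirected graph with strictly positive edge weights, per-node *sizes*
(all 1 for a raw network; summed member sizes after aggregation, so that the
Constant Potts Model pair count is preserved by the Louvain/Leiden recursion)
and per-node *strengths* (weighted degrees).

Self-loop convention
--------------------
A self-loop of weight ``w`` contributes ``2w`` to the strength of its node,
``w`` to the internal weight of whichever community the node belongs to, and
``w`` to the total weight ``m``.  This is the unique convention under which
collapsing a community into a single aggregate node with a self-loop leaves
both modularity and CPM exactly unchanged.

Null-model overrides
--------------------
``null_m`` and ``null_strengths`` default to the graph's own totals.  An
induced subgraph can retain the *parent* graph's values (``keep_null=True``)
so that modularity evaluated on the subgraph uses the full network's ``2m``
and original degrees — the "consistent" subnetwork objective needed when a
community's own subnetwork is re-clustered during an audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Graph",
    "Partition",
    "GraphParseError",
    "load_edge_list",
    "write_partition_tsv",
    "read_partition_tsv",
    "aggregate",
    "induced_subgraph",
    "connected_components",
]


class GraphParseError(ValueError):
    """Raised when an edge-list or partition file cannot be parsed."""


@dataclass
class Graph:
    """Undirected weighted graph with node sizes and cached strengths.

    Parameters
    ----------
    n : int
        Number of nodes; ids are ``0..n-1``.
    edges : dict[(int, int), float]
        Unordered edges keyed by ``(u, v)`` with ``u <= v``; ``u == v`` is a
        self-loop.  Weights must be strictly positive.
    node_sizes : array-like of float, optional
        Per-node sizes (default 1.0).
    labels : sequence of str, optional
        External node labels, in id order, for round-tripping user files.
    """

    n: int
    edges: dict = field(default_factory=dict)
    node_sizes: np.ndarray | None = None
    labels: Sequence[str] | None = None
    null_m: float | None = None
    null_strengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.node_sizes is None:
            self.node_sizes = np.ones(self.n)
        else:
            self.node_sizes = np.asarray(self.node_sizes, dtype=float)
            if np.any(self.node_sizes <= 0):
                raise ValueError("node sizes must be strictly positive")
        # adjacency excludes self-loops; those live in self_weight
        self.adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
        self.self_weight = np.zeros(self.n)
        for (u, v), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"edge ({u},{v}) has non-positive weight {w}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) out of range for n={self.n}")
            if u == v:
                self.self_weight[u] += w
            else:
                self.adj[u].append((v, w))
                self.adj[v].append((u, w))
        self.strengths = np.array(
            [sum(w for _, w in nbrs) for nbrs in self.adj]
        ) + 2.0 * self.self_weight
        self.m = float(self.strengths.sum()) / 2.0
        if self.null_m is None:
            self.null_m = self.m
        if self.null_strengths is None:
            self.null_strengths = self.strengths.copy()
        else:
            self.null_strengths = np.asarray(self.null_strengths, dtype=float)

    @property
    def node_count(self) -> int:
        return self.n

    def neighbors(self, v: int) -> list[tuple[int, float]]:
        return self.adj[v]

    def degree_weight(self, v: int) -> float:
        return float(self.strengths[v])

    def edge_count(self) -> int:
        return len(self.edges)

    def total_size(self) -> float:
        return float(self.node_sizes.sum())

    def label_of(self, v: int) -> str:
        return self.labels[v] if self.labels is not None else str(v)


class Partition:
    """Node→community assignment with cached per-community aggregates.

    Community labels are contiguous integers ``0..C-1``.  Cached per
    community: internal edge weight ``E_c`` (each unordered pair once,
    self-loops fully internal), strength sum ``K_c`` (from the graph's
    null strengths, so modularity stays consistent under subnetwork
    audits), size sum ``n_c`` and member count.
    """

    def __init__(self, graph: Graph, membership: Iterable[int]):
        self.graph = graph
        memb = np.asarray(list(membership), dtype=np.int64)
        if memb.shape != (graph.n,):
            raise ValueError("membership length must equal node count")
        # relabel to contiguous 0..C-1 in first-appearance order
        uniq, inv = np.unique(memb, return_inverse=True)
        order = np.empty(len(uniq), dtype=np.int64)
        seen: dict[int, int] = {}
        nxt = 0
        for c in memb:
            if c not in seen:
                seen[c] = nxt
                nxt += 1
        remap = np.array([seen[c] for c in uniq])
        self.membership = remap[inv]
        self.n_communities = nxt
        self._recompute_aggregates()

    @classmethod
    def singleton(cls, graph: Graph) -> "Partition":
        return cls(graph, np.arange(graph.n))

    @classmethod
    def all_in_one(cls, graph: Graph) -> "Partition":
        return cls(graph, np.zeros(graph.n, dtype=np.int64))

    def _recompute_aggregates(self) -> None:
        g = self.graph
        C = self.n_communities
        self.internal_weight = np.zeros(C)
        self.degree_sum = np.zeros(C)
        self.size_sum = np.zeros(C)
        self.counts = np.zeros(C, dtype=np.int64)
        memb = self.membership
        for v in range(g.n):
            c = memb[v]
            self.degree_sum[c] += g.null_strengths[v]
            self.size_sum[c] += g.node_sizes[v]
            self.counts[c] += 1
            self.internal_weight[c] += g.self_weight[v]
        for (u, v), w in g.edges.items():
            if u != v and memb[u] == memb[v]:
                self.internal_weight[memb[u]] += w

    def copy(self) -> "Partition":
        return Partition(self.graph, self.membership.copy())

    def community_of(self, v: int) -> int:
        return int(self.membership[v])

    def members(self, c: int) -> np.ndarray:
        return np.nonzero(self.membership == c)[0]

    def communities(self) -> list[np.ndarray]:
        return [self.members(c) for c in range(self.n_communities)]

    def weight_to_community(self, v: int, c: int) -> float:
        """Total edge weight from ``v`` to community ``c``, excluding any
        self-loop of ``v``."""
        memb = self.membership
        return sum(w for u, w in self.graph.adj[v] if memb[u] == c)

    def weight_between(self, c1: int, c2: int) -> float:
        """Total edge weight between two distinct communities."""
        if c1 == c2:
            raise ValueError("communities must be distinct")
        a, b = (c1, c2) if self.counts[c1] <= self.counts[c2] else (c2, c1)
        memb = self.membership
        total = 0.0
        for v in self.members(a):
            total += sum(w for u, w in self.graph.adj[v] if memb[u] == b)
        return total

    def move(self, v: int, target: int, compact: bool = True) -> None:
        """Move node ``v`` to community ``target``, updating aggregates in
        O(deg v).  ``target == n_communities`` opens a fresh community.
        With ``compact=True`` (default) empty communities left behind are
        compacted away by relabelling; ``compact=False`` keeps labels
        stable (possibly leaving empty labels) for callers that track
        communities by label during a batch of moves."""
        g = self.graph
        old = int(self.membership[v])
        if target == self.n_communities:
            self.internal_weight = np.append(self.internal_weight, 0.0)
            self.degree_sum = np.append(self.degree_sum, 0.0)
            self.size_sum = np.append(self.size_sum, 0.0)
            self.counts = np.append(self.counts, 0)
            self.n_communities += 1
        if target == old:
            if compact:
                self._maybe_compact(old)
            return
        w_old = self.weight_to_community(v, old)
        w_new = self.weight_to_community(v, target)
        sl = g.self_weight[v]
        self.internal_weight[old] -= w_old + sl
        self.internal_weight[target] += w_new + sl
        self.degree_sum[old] -= g.null_strengths[v]
        self.degree_sum[target] += g.null_strengths[v]
        self.size_sum[old] -= g.node_sizes[v]
        self.size_sum[target] += g.node_sizes[v]
        self.counts[old] -= 1
        self.counts[target] += 1
        self.membership[v] = target
        if compact:
            self._maybe_compact(old)

    def _maybe_compact(self, c: int) -> None:
        if self.counts[c] > 0:
            # also drop a trailing never-used fresh community
            if self.counts[self.n_communities - 1] == 0:
                self._drop(self.n_communities - 1)
            return
        self._drop(c)

    def _drop(self, c: int) -> None:
        last = self.n_communities - 1
        if c != last:
            self.membership[self.membership == last] = c
            for arr in (self.internal_weight, self.degree_sum, self.size_sum,
                        self.counts):
                arr[c] = arr[last]
        self.internal_weight = self.internal_weight[:last]
        self.degree_sum = self.degree_sum[:last]
        self.size_sum = self.size_sum[:last]
        self.counts = self.counts[:last]
        self.n_communities = last

    def equivalent_to(self, other: "Partition") -> bool:
        """Label-permutation-invariant equality of the two clusterings."""
        if self.graph.n != other.graph.n:
            return False
        fwd: dict[int, int] = {}
        bwd: dict[int, int] = {}
        for a, b in zip(self.membership, other.membership):
            a, b = int(a), int(b)
            if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
                return False
        return True


def load_edge_list(path, weighted: bool = True) -> Graph:
    """Read a whitespace-separated ``u v [w]`` edge list into a :class:`Graph`.

    Lines starting with ``#`` are comments.  Node labels are arbitrary
    strings, mapped to contiguous integer ids in first-appearance order;
    duplicate ``(u, v)`` lines have their weights summed.
    """
    ids: dict[str, int] = {}
    labels: list[str] = []
    edges: dict[tuple[int, int], float] = {}

    def nid(tok: str) -> int:
        if tok not in ids:
            ids[tok] = len(labels)
            labels.append(tok)
        return ids[tok]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) == 2:
                u, v, w = toks[0], toks[1], 1.0
            elif len(toks) == 3 and weighted:
                u, v = toks[0], toks[1]
                try:
                    w = float(toks[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path}:{lineno}: bad weight {toks[2]!r}"
                    ) from exc
            else:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 or 3 tokens, got {len(toks)}"
                )
            if w <= 0:
                raise GraphParseError(
                    f"{path}:{lineno}: non-positive weight {w}"
                )
            iu, iv = nid(u), nid(v)
            key = (iu, iv) if iu <= iv else (iv, iu)
            edges[key] = edges.get(key, 0.0) + w
    return Graph(len(labels), edges, labels=labels)


def write_edge_list(graph: Graph, path) -> None:
    """Write a graph back to ``u v w`` text, one line per unordered edge."""
    with open(path, "w") as fh:
        for (u, v), w in sorted(graph.edges.items()):
            fh.write(f"{graph.label_of(u)}\t{graph.label_of(v)}\t{w:g}\n")


def write_partition_tsv(graph: Graph, partition: Partition, path) -> None:
    """Write ``node<TAB>community`` using the graph's original labels."""
    with open(path, "w") as fh:
        for v in range(graph.n):
            fh.write(f"{graph.label_of(v)}\t{partition.membership[v]}\n")


def read_partition_tsv(graph: Graph, path) -> Partition:
    """Read a ``node<TAB>community`` file for ``graph``."""
    by_label = {graph.label_of(v): v for v in range(graph.n)}
    memb = np.full(graph.n, -1, dtype=np.int64)
    comm_ids: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(toks)}"
                )
            node, comm = toks
            if node not in by_label:
                raise GraphParseError(f"{path}:{lineno}: unknown node {node!r}")
            if comm not in comm_ids:
                comm_ids[comm] = len(comm_ids)
            memb[by_label[node]] = comm_ids[comm]
    if np.any(memb < 0):
        missing = [graph.label_of(v) for v in np.nonzero(memb < 0)[0][:5]]
        raise GraphParseError(f"{path}: nodes without community: {missing}")
    return Partition(graph, memb)


def aggregate(graph: Graph, partition: Partition) -> tuple[Graph, np.ndarray]:
    """Collapse each community into one node.

    Aggregate node ``c`` carries size ``n_c``, a self-loop of weight ``E_c``
    and inter-community weights as plain edges; ``m`` and total node size
    are conserved exactly, and so is the quality of the induced partition.
    Returns the aggregate graph and the community→aggregate-node map
    (identity over community labels).
    """
    memb = partition.membership
    C = partition.n_communities
    edges: dict[tuple[int, int], float] = {}
    for c in range(C):
        ew = partition.internal_weight[c]
        if ew > 0:
            edges[(c, c)] = float(ew)
    for (u, v), w in graph.edges.items():
        cu, cv = int(memb[u]), int(memb[v])
        if cu != cv:
            key = (cu, cv) if cu <= cv else (cv, cu)
            edges[key] = edges.get(key, 0.0) + w
    sizes = partition.size_sum.copy()
    null_strengths = partition.degree_sum.copy()
    agg = Graph(C, edges, node_sizes=sizes,
                null_m=graph.null_m, null_strengths=null_strengths)
    return agg, np.arange(C)


def induced_subgraph(
    graph: Graph, nodes: Iterable[int], keep_null: bool = False
) -> tuple[Graph, dict[int, int]]:
    """Subgraph on ``nodes`` keeping only internal edges.

    With ``keep_null=True`` the subgraph retains the parent graph's total
    weight and per-node strengths as its modularity null model, so that
    optimising modularity on the subgraph is consistent with optimising it
    on the whole network.
    Returns the subgraph and the original→new id map.
    """
    node_list = sorted(set(int(v) for v in nodes))
    if not node_list:
        raise ValueError("node set must be nonempty")
    idmap = {v: i for i, v in enumerate(node_list)}
    edges = {}
    for (u, v), w in graph.edges.items():
        if u in idmap and v in idmap:
            edges[(idmap[u], idmap[v])] = w
    sizes = graph.node_sizes[node_list]
    labels = [graph.label_of(v) for v in node_list]
    if keep_null:
        sub = Graph(len(node_list), edges, node_sizes=sizes, labels=labels,
                    null_m=graph.null_m,
                    null_strengths=graph.null_strengths[node_list])
    else:
        sub = Graph(len(node_list), edges, node_sizes=sizes, labels=labels)
    return sub, idmap


def connected_components(graph: Graph) -> list[list[int]]:
    """Connected components as node lists, ordered by smallest member id."""
    seen = np.zeros(graph.n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(graph.n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for u, _ in graph.adj[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(sorted(comp))
    return comps
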