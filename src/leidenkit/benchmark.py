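"""Planted-partition benchmark generator, γ-from-μ rule, recovery scoring,
and the certified bridge fixture that triggers the Louvain pathology.

The benchmark places ``n`` nodes into equal-size communities and draws a
fixed number of distinct edges, ``round(n·⟨k⟩/2)``: each edge falls
between two communities with probability μ and within a community with
probability 1 − μ.  The defaults mirror the standard study conditions:
community size 50 and average degree ⟨k⟩ = 10.

For CPM, the resolution is set from μ as the midpoint between the
expected intra-community density ``p_in = (1−μ)·⟨k⟩/(c−1)`` and the
expected inter-community density ``p_out = μ·⟨k⟩/(n−c)`` — the density
threshold semantics of the CPM resolution parameter (communities denser
than γ inside, sparser than γ between).

The bridge fixture realises, in miniature, the mechanism by which local
moving disconnects a community: a hub node bridges two internally tied
triads and is pulled away by an external community, leaving the triads in
a disconnected community in which no single node has an improving move.
The fixture is certified by explicit delta checks at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .graph import Graph, Partition
from .louvain import best_move
from .quality import CPM, EPS, QualitySpec, delta_move, delta_merge, quality

__all__ = [
    "BenchmarkSpec",
    "ResolutionResult",
    "RecoveryScore",
    "generate_benchmark",
    "resolution_from_mu",
    "score_recovery",
    "scaled_quality",
    "make_bridge_fixture",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Planted-partition parameters.

    n : total nodes; must be divisible by ``community_size``.
    community_size : nodes per planted community (default 50).
    avg_degree : target mean degree ⟨k⟩ (default 10).
    mu : probability that an edge falls between communities.
    seed : generator seed.
    """

    n: int = 1000
    community_size: int = 50
    avg_degree: float = 10.0
    mu: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.community_size < 2:
            raise ValueError("community_size must be >= 2")
        if self.n < 2 * self.community_size:
            raise ValueError("need at least two communities")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        if self.avg_degree >= self.n - 1:
            raise ValueError("avg_degree must be < n - 1")

    @property
    def n_communities(self) -> int:
        return self.n // self.community_size

    @property
    def n_edges(self) -> int:
        return round(self.n * self.avg_degree / 2.0)


def generate_benchmark(spec: BenchmarkSpec) -> tuple[Graph, Partition]:
    """Draw a planted-partition graph; returns (graph, planted partition).

    Exactly ``round(n·⟨k⟩/2)`` distinct edges; self-loops and duplicates
    are rejection-resampled.  Deterministic for a given spec and seed.
    """
    if spec.n % spec.community_size != 0:
        raise ValueError("n must be divisible by community_size")
    C = spec.n_communities
    capacity = spec.n * (spec.n - 1) // 2
    if spec.n_edges > capacity:
        raise ValueError("requested edges exceed simple-graph capacity")
    rng = np.random.default_rng(spec.seed)
    membership = np.repeat(np.arange(C), spec.community_size)
    edges: dict[tuple[int, int], float] = {}
    # the inter/intra label is drawn first, so the inter-community edge
    # count is exactly Binomial(n_edges, mu); duplicate or self pairs are
    # rejection-resampled *within* their category, which keeps the mixing
    # fraction unbiased (resampling across categories would skew it,
    # because intra pairs collide far more often than inter pairs)
    for _ in range(spec.n_edges):
        inter = rng.random() < spec.mu
        for _attempt in range(100000):
            if inter:
                c1, c2 = rng.choice(C, size=2, replace=False)
                u = int(rng.integers(spec.community_size)) \
                    + int(c1) * spec.community_size
                v = int(rng.integers(spec.community_size)) \
                    + int(c2) * spec.community_size
            else:
                c = int(rng.integers(C))
                u, v = rng.choice(spec.community_size, size=2, replace=False)
                u = int(u) + c * spec.community_size
                v = int(v) + c * spec.community_size
            key = (u, v) if u < v else (v, u)
            if key not in edges:
                edges[key] = 1.0
                break
        else:
            raise ValueError("could not place a distinct edge; requested "
                             "edge count too close to category capacity")
    graph = Graph(spec.n, edges)
    return graph, Partition(graph, membership)


@dataclass(frozen=True)
class ResolutionResult:
    gamma: float
    p_in: float
    p_out: float
    detectable: bool  # False when p_in <= p_out: density cannot separate


def resolution_from_mu(spec: BenchmarkSpec) -> ResolutionResult:
    """CPM resolution from the mixing parameter: midpoint of the expected
    intra- and inter-community densities."""
    p_in = (1.0 - spec.mu) * spec.avg_degree / (spec.community_size - 1)
    p_out = spec.mu * spec.avg_degree / (spec.n - spec.community_size)
    return ResolutionResult(
        gamma=(p_in + p_out) / 2.0,
        p_in=p_in,
        p_out=p_out,
        detectable=p_in > p_out,
    )


@dataclass(frozen=True)
class RecoveryScore:
    exact_match: bool
    ari: float
    nmi: float


def score_recovery(found: Partition, planted: Partition) -> RecoveryScore:
    """Compare a found partition with the planted one.

    ``exact_match`` is label-permutation-invariant equality; ARI and NMI
    are the usual chance-corrected pair-counting and information scores.
    """
    a = found.membership
    b = planted.membership
    return RecoveryScore(
        exact_match=found.equivalent_to(planted),
        ari=float(adjusted_rand_score(b, a)),
        nmi=float(normalized_mutual_info_score(b, a)),
    )


def scaled_quality(graph: Graph, partition: Partition,
                   spec: QualitySpec) -> float:
    """Quality divided by 2m — the scale benchmark results are reported on."""
    return quality(graph, partition, spec) / (2.0 * graph.m)


def make_bridge_fixture(
    n_satellites: int = 8, seed: int = 0
) -> tuple[Graph, Partition, QualitySpec]:
    """Certified fixture on which greedy local moving disconnects a community.

    Node 0 bridges two triads (1–3 and 4–6) with weak edges and is also
    connected to every node of an external clique of ``n_satellites``
    nodes.  Under modularity at γ = 1, starting from the partition
    {0..6 | satellites}:

    * moving node 0 to the satellite community strictly improves quality;
    * after that move, no node in 1..6 has an improving single move, so
      the (now disconnected) triad community survives local moving.

    Both facts, and the resulting two-component structure, are certified
    by delta checks at construction; failure raises ``RuntimeError``.
    Returns (graph, adversarial start partition, quality spec).
    """
    if n_satellites < 2:
        raise ValueError("need at least 2 satellite nodes")
    strong = 10.0   # intra-triad ties
    weak = 1.0      # hub-triad bridges
    pull = 2.0      # hub-satellite edges
    edges: dict[tuple[int, int], float] = {}
    # hub 0 bridges the two triads
    edges[(0, 1)] = weak
    edges[(0, 4)] = weak
    for a, b in [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)]:
        edges[(a, b)] = strong
    sat = list(range(7, 7 + n_satellites))
    for i, u in enumerate(sat):
        edges[(0, u)] = pull
        for v in sat[i + 1:]:
            edges[(u, v)] = 1.0
    graph = Graph(7 + n_satellites, edges)
    start = Partition(graph, [0] * 7 + [1] * n_satellites)
    spec = QualitySpec("modularity", 1.0)

    sat_comm = start.community_of(sat[0])
    d_hub = delta_move(graph, start, 0, sat_comm, spec)
    if d_hub <= EPS:
        raise RuntimeError("fixture certification failed: hub move not "
                           f"improving (delta={d_hub})")
    moved = start.copy()
    moved.move(0, sat_comm)
    for v in range(1, 7):
        _, d = best_move(graph, moved, v, spec)
        if d > EPS:
            raise RuntimeError("fixture certification failed: node "
                               f"{v} still has an improving move ({d})")
    from .graph import connected_components, induced_subgraph

    triads = moved.members(moved.community_of(1))
    sub, _ = induced_subgraph(graph, triads)
    if len(connected_components(sub)) != 2:
        raise RuntimeError("fixture certification failed: expected exactly "
                           "2 components after the hub move")
    for c1 in range(moved.n_communities):
        for c2 in range(c1 + 1, moved.n_communities):
            if delta_merge(graph, moved, c1, c2, spec) > EPS:
                raise RuntimeError("fixture certification failed: "
                                   "post-move partition not separated")
    return graph, start, spec
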