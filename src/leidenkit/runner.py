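"""Iterated runs of either algorithm, with per-iteration records.

Both Louvain and Leiden are meant to be run iteratively, feeding the
partition found by one iteration into the next.  An iteration that leaves
the partition unchanged is a *stable* iteration.  For Louvain every
iteration after a stable one is stable too; for Leiden the randomized
refinement means a stable iteration can still be followed by an improving
one, which is why the ``until_converged`` policy demands two consecutive
unchanged iterations (and re-checks node optimality and γ-separation).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, Partition
from .leiden import (
    FIXED_ITERATIONS,
    UNTIL_CONVERGED,
    UNTIL_STABLE,
    LeidenConfig,
    leiden_iteration,
)
from .louvain import louvain_iteration
from .quality import QualitySpec, quality

__all__ = ["IterationRecord", "RunRecord", "iterate", "run_leiden",
           "run_louvain"]


@dataclass
class IterationRecord:
    quality: float
    n_communities: int
    wall_time: float
    changed: bool


@dataclass
class RunRecord:
    """Trajectory of an iterated run plus the final partition."""

    algorithm: str
    objective: str
    gamma: float
    theta: float | None
    seed: int
    iterations: list[IterationRecord] = field(default_factory=list)
    final_partition: Partition | None = None
    stable_iteration: int | None = None  # 0-based index of first stable one

    @property
    def qualities(self) -> list[float]:
        return [it.quality for it in self.iterations]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "objective": self.objective,
            "gamma": self.gamma,
            "theta": self.theta,
            "seed": self.seed,
            "stable_iteration": self.stable_iteration,
            "n_communities": (None if self.final_partition is None
                              else self.final_partition.n_communities),
            "iterations": [
                {"quality": it.quality, "n_communities": it.n_communities,
                 "wall_time": it.wall_time, "changed": it.changed}
                for it in self.iterations
            ],
        }


def iterate(
    graph: Graph,
    spec: QualitySpec,
    algorithm: str,
    config: LeidenConfig,
    initial: Partition | None = None,
) -> RunRecord:
    """Run ``algorithm`` (``"louvain"`` or ``"leiden"``) iteratively.

    Starts from ``initial`` (default: singleton partition) and records the
    quality trajectory, community counts and the first stable iteration.
    Reproducible given ``config.seed``.
    """
    if algorithm not in ("louvain", "leiden"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(config.seed)
    p = initial.copy() if initial is not None else Partition.singleton(graph)
    record = RunRecord(
        algorithm=algorithm,
        objective=spec.objective,
        gamma=spec.gamma,
        theta=config.theta if algorithm == "leiden" else None,
        seed=config.seed,
    )
    consecutive_stable = 0
    for _ in range(config.max_iterations):
        t0 = time.perf_counter()
        if algorithm == "leiden":
            nxt = leiden_iteration(graph, p, spec, config, rng)
        else:
            nxt = louvain_iteration(graph, p, spec, rng)
        dt = time.perf_counter() - t0
        changed = not np.array_equal(
            _canon(nxt.membership), _canon(p.membership)
        )
        record.iterations.append(IterationRecord(
            quality=quality(graph, nxt, spec),
            n_communities=nxt.n_communities,
            wall_time=dt,
            changed=changed,
        ))
        p = nxt
        if not changed:
            if record.stable_iteration is None:
                record.stable_iteration = len(record.iterations) - 1
            consecutive_stable += 1
        else:
            consecutive_stable = 0
        if config.stop_policy == UNTIL_STABLE and not changed:
            break
        if config.stop_policy == UNTIL_CONVERGED and consecutive_stable >= 2:
            from .guarantees import is_gamma_separated, is_node_optimal

            if (is_node_optimal(graph, p, spec)
                    and is_gamma_separated(graph, p, spec)):
                break
            consecutive_stable = 0
    record.final_partition = p
    return record


def _canon(membership: np.ndarray) -> np.ndarray:
    """Canonical first-appearance relabelling, for change detection."""
    seen: dict[int, int] = {}
    out = np.empty_like(membership)
    for i, c in enumerate(membership):
        c = int(c)
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out


def run_leiden(
    graph: Graph,
    spec: QualitySpec,
    config: LeidenConfig | None = None,
    initial: Partition | None = None,
) -> RunRecord:
    """Convenience wrapper: iterated Leiden run."""
    return iterate(graph, spec, "leiden", config or LeidenConfig(),
                   initial=initial)


def run_louvain(
    graph: Graph,
    spec: QualitySpec,
    config: LeidenConfig | None = None,
    initial: Partition | None = None,
) -> RunRecord:
    """Convenience wrapper: iterated Louvain run."""
    return iterate(graph, spec, "louvain", config or LeidenConfig(),
                   initial=initial)
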