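"""Classical TSP heuristic: nearest-neighbour construction plus 2-opt local search.

The tour always starts (and ends) at the artificial vertex 0, so removing it
from the Hamiltonian cycle yields the read ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .overlap import CostMatrix


@dataclass
class TspSolution:
    """A Hamiltonian cycle through all vertices, anchored at vertex 0."""

    cycle: list[int]  # [0, v1, ..., vN, 0]
    cost: int
    meta: dict = field(default_factory=dict)

    @property
    def path(self) -> list[int]:
        """Vertex order with the artificial vertex removed."""
        return [v for v in self.cycle[:-1] if v != 0]

    def read_order(self, cm: CostMatrix) -> list[str]:
        return [cm.read_ids[v - 1] for v in self.path]


def _as_array(cost) -> np.ndarray:
    c = cost.cost if isinstance(cost, CostMatrix) else np.asarray(cost)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {c.shape}")
    if not np.array_equal(c, c.T):
        raise ValueError("cost matrix must be symmetric")
    if (c < 0).any():
        raise ValueError("cost matrix must be non-negative")
    return c


def tour_cost(cycle: list[int], cost) -> int:
    """Sum of consecutive edge costs along the closed cycle."""
    c = _as_array(cost)
    n = c.shape[0]
    if cycle[0] != cycle[-1]:
        raise ValueError("cycle must be closed (first vertex == last vertex)")
    visited = cycle[:-1]
    if sorted(visited) != list(range(n)):
        raise ValueError("cycle must visit every vertex exactly once")
    return int(sum(c[cycle[k], cycle[k + 1]] for k in range(len(cycle) - 1)))


def solve_nn(cost, start: int = 0) -> TspSolution:
    """Greedy nearest-neighbour tour from ``start``; ties broken by lowest index."""
    c = _as_array(cost)
    n = c.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices (artificial vertex + 1 read)")
    unvisited = np.ones(n, dtype=bool)
    unvisited[start] = False
    cycle = [start]
    cur = start
    for _ in range(n - 1):
        dist = np.where(unvisited, c[cur], np.inf)
        nxt = int(np.argmin(dist))  # argmin returns the lowest index on ties
        cycle.append(nxt)
        unvisited[nxt] = False
        cur = nxt
    cycle.append(start)
    return TspSolution(cycle=cycle, cost=tour_cost(cycle, c), meta={"solver": "nn"})


def improve_2opt(sol: TspSolution, cost, max_passes: int = 50) -> TspSolution:
    """First-improvement 2-opt; never increases cost, keeps vertex 0 first."""
    c = _as_array(cost)
    cycle = list(sol.cycle)
    n = len(cycle) - 1  # number of distinct vertices
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        # reverse cycle[i:j+1]; endpoints cycle[0] and cycle[-1] stay put
        for i in range(1, n - 1):
            for j in range(i + 1, n):
                a, b = cycle[i - 1], cycle[i]
                d, e = cycle[j], cycle[j + 1]
                delta = (c[a, d] + c[b, e]) - (c[a, b] + c[d, e])
                if delta < 0:
                    cycle[i : j + 1] = reversed(cycle[i : j + 1])
                    improved = True
    return TspSolution(
        cycle=cycle,
        cost=tour_cost(cycle, c),
        meta={**sol.meta, "solver": sol.meta.get("solver", "?") + "+2opt", "passes": passes},
    )


def improve_oropt(sol: TspSolution, cost, max_passes: int = 50) -> TspSolution:
    """Or-opt: relocate segments of 1-3 vertices to a cheaper position."""
    c = _as_array(cost)
    cycle = list(sol.cycle)
    n = len(cycle) - 1
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for seg_len in (1, 2, 3):
            for i in range(1, n - seg_len + 1):
                seg = cycle[i : i + seg_len]
                rest = cycle[:i] + cycle[i + seg_len :]
                removed = (
                    c[cycle[i - 1], seg[0]]
                    + c[seg[-1], cycle[i + seg_len]]
                    - c[cycle[i - 1], cycle[i + seg_len]]
                )
                for k in range(1, len(rest) - 1):
                    added = c[rest[k - 1], seg[0]] + c[seg[-1], rest[k]] - c[rest[k - 1], rest[k]]
                    if added < removed:
                        cycle = rest[:k] + seg + rest[k:]
                        improved = True
                        break
    return TspSolution(
        cycle=cycle,
        cost=tour_cost(cycle, c),
        meta={**sol.meta, "solver": sol.meta.get("solver", "?") + "+oropt"},
    )


def solve_classic(cost, max_passes: int = 50) -> TspSolution:
    """Nearest neighbour from the artificial vertex, refined with alternating
    2-opt and or-opt local search until neither improves."""
    sol = solve_nn(cost, start=0)
    prev = None
    while prev is None or sol.cost < prev:
        prev = sol.cost
        sol = improve_2opt(sol, cost, max_passes=max_passes)
        sol = improve_oropt(sol, cost, max_passes=max_passes)
    return sol
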