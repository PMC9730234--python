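"""Open-path scan-order optimization by fast simulated annealing.

Delivering one energy group is an open-path travelling-salesman problem: the
robotic arm must visit every scan spot once, cost = summed Euclidean distance,
with no return leg (the next stop is an energy switch, not the first spot).
Each group is optimized independently because an energy switch (seconds)
dwarfs any single arm move (tens of milliseconds).

The annealer starts from the zigzag order and uses a fast cooling schedule,
``T(k) = T0 · k^(−1/N)`` with N the group's spot count, together with
heavy-tailed (Cauchy) move proposals: candidate moves are 2-opt segment
reversals whose extent is drawn from a standard Cauchy scaled by the current
temperature, so early iterations make occasional long jumps across the
solution space while late ones refine locally.  Worsening moves are accepted
with Metropolis probability ``exp(−Δf/T)``; the best order seen is returned,
so the result never exceeds the zigzag length.

A brute-force exhaustive solver (N ≤ 10) serves as the exact oracle for
small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .sequencer import EnergyGroup, ScanPlan, reorder_group

__all__ = [
    "FSAConfig",
    "PathSolution",
    "PlanOptimizationResult",
    "path_length",
    "fsa_optimize",
    "brute_force_optimal",
    "optimize_plan",
]


@dataclass(frozen=True)
class FSAConfig:
    """Annealing budget and schedule.

    ``t0=None`` sets the initial temperature to half the initial path length,
    large enough that almost all early transitions are accepted.  The default
    budget is ``iterations`` temperature steps of ``N`` moves each (1000·N
    moves per restart) with 3 restarts, best kept.
    """

    t0: float | None = None  # path-length units; None = 0.5 * initial length
    iterations: int = 1000
    moves_per_iteration: int | None = None  # None = one move per spot
    seed: int = 0
    restarts: int = 3
    schedule: Literal["power", "classic"] = "power"

    def __post_init__(self) -> None:
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.iterations < 1 or self.restarts < 1:
            raise ValueError("iterations and restarts must be >= 1")


@dataclass(frozen=True)
class PathSolution:
    """An optimized visiting order with its length bookkeeping.

    ``order`` permutes the input spot indices; ``delta_s`` is the percent
    change of path length relative to the initial (zigzag) order, hence
    never positive.
    """

    order: tuple[int, ...]
    length: float
    initial_length: float

    def __post_init__(self) -> None:
        if self.length > self.initial_length + 1e-9:
            raise ValueError("solution length must not exceed the initial length")

    @property
    def delta_s(self) -> float:
        """Percent change in path length; 0 for a zero-length initial path."""
        if self.initial_length == 0:
            return 0.0
        return 100.0 * (self.length - self.initial_length) / self.initial_length


def path_length(positions: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Length (mm) of the open path visiting positions in the given order."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) == 0:
        raise ValueError("positions must be a non-empty (N, 2) array")
    if len(pos) == 1:
        return 0.0
    return float(np.hypot(*np.diff(pos, axis=0).T).sum())


def _distance_matrix(pos: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def _open_path_cost(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def fsa_optimize(group: EnergyGroup, config: FSAConfig = FSAConfig()) -> PathSolution:
    """Anneal a group's scan order starting from its current (zigzag) order.

    Deterministic for a fixed ``(group, config)``; groups of one or two
    spots are returned unchanged (every order is already optimal).
    """
    n = len(group)
    pos = group.positions()
    identity = tuple(range(n))
    if n <= 2:
        length = path_length(pos)
        return PathSolution(identity, length, length)

    dist = _distance_matrix(pos)
    initial_length = _open_path_cost(np.arange(n), dist)
    if initial_length == 0.0:
        return PathSolution(identity, 0.0, 0.0)
    t0 = config.t0 if config.t0 is not None else 0.5 * initial_length
    moves = config.moves_per_iteration or n
    rng = np.random.default_rng(config.seed)

    best_order = list(identity)
    best_len = initial_length
    for _ in range(config.restarts):
        cur = list(identity)
        cur_len = initial_length
        for k in range(1, config.iterations + 1):
            if config.schedule == "power":
                temp = t0 * k ** (-1.0 / n)
            else:
                temp = t0 / k
            # Cauchy-scaled reversal extent: long jumps while hot, local when cold
            scale = max(1.0, (temp / t0) * n)
            for _ in range(moves):
                i = int(rng.integers(0, n - 1))
                extent = int(round(abs(rng.standard_cauchy()) * scale))
                j = min(n - 1, i + max(1, extent))
                # 2-opt: reversing cur[i..j] touches only the two boundary edges
                a = dist[cur[i - 1], cur[j]] - dist[cur[i - 1], cur[i]] if i > 0 else 0.0
                b = (
                    dist[cur[i], cur[j + 1]] - dist[cur[j], cur[j + 1]]
                    if j < n - 1
                    else 0.0
                )
                delta = a + b
                if delta <= 0.0 or rng.random() < math.exp(-delta / temp):
                    cur[i : j + 1] = cur[i : j + 1][::-1]
                    cur_len += delta
                    if cur_len < best_len - 1e-12:
                        best_order = cur.copy()
                        best_len = cur_len

    exact = _open_path_cost(np.asarray(best_order), dist)
    if exact > initial_length:  # pragma: no cover - guards float drift only
        best_order, exact = list(identity), initial_length
    return PathSolution(tuple(best_order), exact, initial_length)


def brute_force_optimal(group: EnergyGroup, max_n: int = 10) -> PathSolution:
    """Exact open-path optimum by exhaustive permutation search (N ≤ 10).

    Every visiting order is enumerated (a path and its reverse have equal
    length, so both appear); ties at the global minimum break to the
    lexicographically smallest index order.
    """
    n = len(group)
    if n > max_n:
        raise ValueError(f"brute force refused for N={n} > {max_n}")
    pos = group.positions()
    identity = np.arange(n)
    if n <= 2:
        length = path_length(pos)
        return PathSolution(tuple(range(n)), length, length)
    dist = _distance_matrix(pos)
    initial_length = _open_path_cost(identity, dist)

    best_len = math.inf
    best_order: tuple[int, ...] | None = None
    chunk = 40320  # 8! permutations at a time keeps memory flat
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        perms = np.array(block, dtype=np.intp)
        lengths = dist[perms[:, :-1], perms[:, 1:]].sum(axis=1)
        i_min = int(np.argmin(lengths))
        lo = float(lengths[i_min])
        if lo < best_len - 1e-9:
            ties = np.nonzero(lengths <= lo + 1e-9)[0]
            best_order = min(tuple(map(int, perms[t])) for t in ties)
            best_len = lo
        elif lo <= best_len + 1e-9:
            ties = np.nonzero(lengths <= best_len + 1e-9)[0]
            cand = min(tuple(map(int, perms[t])) for t in ties)
            if cand < best_order:
                best_order = cand
            best_len = min(best_len, lo)
    return PathSolution(best_order, min(best_len, initial_length), initial_length)


@dataclass(frozen=True)
class PlanOptimizationResult:
    """Optimized plan plus per-group and total path-length summaries."""

    plan: ScanPlan
    solutions: dict[int, PathSolution] = field(default_factory=dict)

    @property
    def s_initial(self) -> float:
        return sum(s.initial_length for s in self.solutions.values())

    @property
    def s_final(self) -> float:
        return sum(s.length for s in self.solutions.values())

    @property
    def delta_s(self) -> float:
        if self.s_initial == 0:
            return 0.0
        return 100.0 * (self.s_final - self.s_initial) / self.s_initial

    def report(self) -> pd.DataFrame:
        """Per-energy and total rows of S_i, S_f and ΔS%."""
        rows = []
        for eid in sorted(self.solutions):
            sol = self.solutions[eid]
            rows.append(
                {
                    "group": f"E{eid}",
                    "n_spots": len(sol.order),
                    "S_i_mm": sol.initial_length,
                    "S_f_mm": sol.length,
                    "delta_S_percent": round(sol.delta_s, 2),
                }
            )
        rows.append(
            {
                "group": "total",
                "n_spots": self.plan.n_spots,
                "S_i_mm": self.s_initial,
                "S_f_mm": self.s_final,
                "delta_S_percent": round(self.delta_s, 2),
            }
        )
        return pd.DataFrame(rows)


def optimize_plan(plan: ScanPlan, config: FSAConfig = FSAConfig()) -> PlanOptimizationResult:
    """Optimize every energy group of a plan independently.

    Each group gets its own seeded annealer (seed = config.seed + energy_id)
    so groups are statistically independent yet the whole run is
    reproducible.  Inter-group travel is excluded from all path lengths.
    """
    new_groups = []
    solutions: dict[int, PathSolution] = {}
    for g in plan.groups:
        sol = fsa_optimize(
            g,
            FSAConfig(
                t0=config.t0,
                iterations=config.iterations,
                moves_per_iteration=config.moves_per_iteration,
                seed=config.seed + g.energy_id,
                restarts=config.restarts,
                schedule=config.schedule,
            ),
        )
        solutions[g.energy_id] = sol
        new_groups.append(reorder_group(g, list(sol.order)))
    new_plan = ScanPlan(
        n_beam_positions=plan.n_beam_positions,
        groups=tuple(new_groups),
        prescription_gy=plan.prescription_gy,
        provenance={**plan.provenance, "optimizer_seed": config.seed},
    )
    return PlanOptimizationResult(new_plan, solutions)
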