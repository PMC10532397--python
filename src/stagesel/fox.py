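"""FOX metaheuristic: population-based minimization over a bounded box.

The optimizer imitates a red fox hunting under snow. Each agent either
*exploits* — estimates the prey distance from the sound round trip to the
incumbent best position and jumps onto a scaled copy of it — or
*explores* — random-walks around the incumbent best with a step that
shrinks as the shortest observed sound time ``MinT`` and the schedule
``a = 2(1 - it/n_iters)`` decay. Constants follow the algorithm's source:
jump gravity 9.81, jump scalings ``c1 = 0.18`` (north-east jump) and
``c2 = 0.82`` (opposite direction), chosen on a random draw ``p > 0.18``.

A single seeded NumPy generator drives the whole run, so identical seeds
give bitwise-identical traces. Out-of-bounds positions are clipped to the
box before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SearchSpace", "OptimizerRun", "fox_minimize", "CostEvaluationError"]


class CostEvaluationError(RuntimeError):
    """The cost function returned a non-finite value."""


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box: per-dimension lower < upper bounds."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper bounds must be 1-D and of equal length")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchSpace":
        return cls(np.full(dim, lo), np.full(dim, hi))


@dataclass(frozen=True)
class OptimizerRun:
    """Outcome of one seeded optimization run.

    ``trace`` holds the incumbent best cost after each iteration and is
    non-increasing (elitism); ``best_cost`` equals its last entry.
    """

    best_position: np.ndarray
    best_cost: float
    trace: np.ndarray
    seed: int
    n_agents: int
    n_iters: int

    def summary(self) -> dict:
        return {
            "best_cost": float(self.best_cost),
            "best_position": [float(v) for v in self.best_position],
            "seed": self.seed,
            "n_agents": self.n_agents,
            "n_iters": self.n_iters,
        }


def fox_minimize(
    cost: Callable[[np.ndarray], float],
    space: SearchSpace,
    n_agents: int = 30,
    n_iters: int = 100,
    seed: int = 0,
    c1: float = 0.18,
    c2: float = 0.82,
    gravity: float = 9.81,
    x0: Sequence[np.ndarray] | None = None,
) -> OptimizerRun:
    """Minimize ``cost`` over ``space`` with the FOX update rules.

    Parameters
    ----------
    x0
        Optional positions injected into the initial population (replacing
        the first agents). Used e.g. to guarantee that the all-features
        baseline of a wrapper search is part of the swarm.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    if n_iters < 1:
        raise ValueError("need at least 1 iteration")
    lo, hi = space.lower, space.upper
    dim = space.dim
    rng = np.random.default_rng(seed)

    positions = lo + rng.random((n_agents, dim)) * (hi - lo)
    if x0 is not None:
        seeds = np.atleast_2d(np.asarray(x0, dtype=float))
        if seeds.shape[0] > n_agents or seeds.shape[1] != dim:
            raise ValueError("x0 must supply at most n_agents positions of the right dim")
        positions[: seeds.shape[0]] = seeds

    best_position = positions[0].copy()
    best_cost = np.inf
    min_time = np.inf
    trace = np.empty(n_iters)

    for it in range(n_iters):
        np.clip(positions, lo, hi, out=positions)
        for i in range(n_agents):
            c = float(cost(positions[i]))
            if not np.isfinite(c):
                raise CostEvaluationError(
                    f"non-finite cost {c!r} at position {positions[i].tolist()}"
                )
            if c < best_cost:
                best_cost = c
                best_position = positions[i].copy()
        trace[it] = best_cost

        a = 2.0 * (1.0 - it / n_iters)
        for i in range(n_agents):
            r = rng.random()
            p = rng.random()
            if r >= 0.5:  # exploitation: jump onto the located prey
                time = rng.random(dim)
                # sound speed = best/time, so distance travelled = best and
                # the fox-to-prey distance is half of it
                dist_fox_prey = 0.5 * best_position
                tt = time.mean()
                jump = 0.5 * gravity * (tt / 2.0) ** 2
                positions[i] = dist_fox_prey * jump * (c1 if p > 0.18 else c2)
                if tt < min_time:
                    min_time = tt
            else:  # exploration: walk around the best position
                step = (min_time if np.isfinite(min_time) else 1.0) * a
                positions[i] = best_position + rng.standard_normal(dim) * step

    best_position = np.clip(best_position, lo, hi)
    return OptimizerRun(
        best_position=best_position,
        best_cost=float(best_cost),
        trace=trace,
        seed=seed,
        n_agents=n_agents,
        n_iters=n_iters,
    )
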