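"""Iteration-assisted enhanced mother optimization algorithm (IEMOA).

A population metaheuristic for bounded-box continuous minimization modeled on
mother–child interactions, run in three phases per iteration:

* **education** (exploration): each member moves toward the best member
  ("the mother"), ``u' = u + r1·f(t)·(best − r2·u)``;
* **guidance** (exploration): each member moves away from one uniformly chosen
  strictly-worse peer, ``u' = u + r1·f(t)·(u − r2·peer)``;
* **nurturing** (exploitation): a small box-scaled perturbation,
  ``u'_j = u_j + r·(1 − 2r')·f(t)·(upper_j − lower_j)/m``.

with r1, r ~ U(0,1) and r2 ~ U(1,2). The iteration-assisted modification is
the decaying factor ``f(t) = 1 − t/max_iterations`` multiplying every random
step, shifting the search from exploration to exploitation as iterations pass.
Every proposal is clipped to the box and accepted only on strict objective
improvement, so no member ever worsens and the best-so-far trace is
non-increasing.

Determinism: one pseudo-random stream per run, consumed in a fixed order —
phase by phase, member by member, and within the education/guidance phases
coordinate by coordinate (r1 and r2 are per-coordinate vectors; the nurturing
r, r' are per-member scalars).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "IEMOAConfig",
    "Population",
    "OptimizationResult",
    "iteration_factor",
    "initialize_population",
    "education_phase",
    "guidance_phase",
    "nurturing_phase",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box: ``lower[j] < upper[j]`` for every coordinate."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower[j] < upper[j] for all j")

    @property
    def dimension(self) -> int:
        return self.lower.shape[0]

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    @classmethod
    def box(cls, lower: float, upper: float, dimension: int) -> "SearchSpace":
        return cls(np.full(dimension, lower), np.full(dimension, upper))


@dataclass(frozen=True)
class IEMOAConfig:
    population_size: int = 10
    max_iterations: int = 50
    seed: int = 0
    minimize: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Population:
    """Positions with a coherent objective cache (values[i] = f(positions[i]))."""

    positions: np.ndarray
    objective_values: np.ndarray

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def best_index(self) -> int:
        return int(np.argmin(self.objective_values))


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far after init and after each iteration
    evaluations: int


def iteration_factor(t: int, max_iterations: int) -> float:
    """Decaying step-size factor ``1 − t/max_iterations`` in [0, 1]."""
    if not 0 <= t <= max_iterations:
        raise ValueError(f"iteration index {t} outside [0, {max_iterations}]")
    return 1.0 - t / max_iterations


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        raise FloatingPointError(f"objective returned non-finite value at {x!r}")
    return v


def initialize_population(
    space: SearchSpace, objective: Objective, config: IEMOAConfig, rng=None
) -> Population:
    """Uniform draw ``lower + r·(upper − lower)`` per member, cache filled."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    r = rng.random((config.population_size, space.dimension))
    positions = space.lower + r * (space.upper - space.lower)
    values = np.array([_evaluate(objective, p) for p in positions])
    return Population(positions, values)


def _greedy_accept(
    pop: Population, i: int, candidate: np.ndarray, objective: Objective, counter: list[int]
) -> None:
    value = _evaluate(objective, candidate)
    counter[0] += 1
    if value < pop.objective_values[i]:  # strict improvement; ties keep incumbent
        pop.positions[i] = candidate
        pop.objective_values[i] = value


def education_phase(
    pop: Population, objective: Objective, space: SearchSpace, f_t: float, rng,
    counter: list[int] | None = None,
) -> Population:
    """Move each member toward the phase-start best member; greedy accept."""
    counter = counter if counter is not None else [0]
    guide = pop.positions[pop.best_index()].copy()
    m = space.dimension
    for i in range(pop.size):
        r1 = rng.random(m)
        r2 = 1.0 + rng.random(m)
        candidate = space.clip(pop.positions[i] + r1 * f_t * (guide - r2 * pop.positions[i]))
        _greedy_accept(pop, i, candidate, objective, counter)
    return pop


def guidance_phase(
    pop: Population, objective: Objective, space: SearchSpace, f_t: float, rng,
    counter: list[int] | None = None,
) -> Population:
    """Move each member away from a random strictly-worse peer; greedy accept.

    A member with no strictly worse peer (the unique worst, or any member when
    all values tie) is left unchanged.
    """
    counter = counter if counter is not None else [0]
    m = space.dimension
    values_at_start = pop.objective_values.copy()
    for i in range(pop.size):
        worse = np.flatnonzero(values_at_start > values_at_start[i])
        if worse.size == 0:
            continue
        k = worse[rng.integers(worse.size)]
        peer = pop.positions[k]
        r1 = rng.random(m)
        r2 = 1.0 + rng.random(m)
        candidate = space.clip(pop.positions[i] + r1 * f_t * (pop.positions[i] - r2 * peer))
        _greedy_accept(pop, i, candidate, objective, counter)
    return pop


def nurturing_phase(
    pop: Population, objective: Objective, space: SearchSpace, f_t: float, rng,
    counter: list[int] | None = None,
) -> Population:
    """Small neighborhood perturbation scaled by the box width over m."""
    counter = counter if counter is not None else [0]
    m = space.dimension
    width = (space.upper - space.lower) / m
    for i in range(pop.size):
        r = rng.random()
        r_sign = rng.random()
        candidate = space.clip(pop.positions[i] + r * (1.0 - 2.0 * r_sign) * f_t * width)
        _greedy_accept(pop, i, candidate, objective, counter)
    return pop


def optimize(
    objective: Objective, space: SearchSpace, config: IEMOAConfig
) -> OptimizationResult:
    """Full IEMOA run; deterministic under ``config.seed``.

    ``minimize=False`` negates the objective internally and reports the
    un-negated best value and trace.
    """
    sign = 1.0 if config.minimize else -1.0
    inner: Objective = (lambda x: sign * float(objective(x)))
    rng = np.random.default_rng(config.seed)
    counter = [0]
    pop = initialize_population(space, inner, config, rng)
    counter[0] += config.population_size

    best_i = pop.best_index()
    best_pos = pop.positions[best_i].copy()
    best_val = float(pop.objective_values[best_i])
    trace = [best_val]
    for t in range(1, config.max_iterations + 1):
        f_t = iteration_factor(t, config.max_iterations)
        education_phase(pop, inner, space, f_t, rng, counter)
        guidance_phase(pop, inner, space, f_t, rng, counter)
        nurturing_phase(pop, inner, space, f_t, rng, counter)
        i = pop.best_index()
        if pop.objective_values[i] < best_val:
            best_val = float(pop.objective_values[i])
            best_pos = pop.positions[i].copy()
        trace.append(best_val)
    return OptimizationResult(
        best_position=best_pos,
        best_value=sign * best_val,
        trace=sign * np.asarray(trace),
        evaluations=counter[0],
    )
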