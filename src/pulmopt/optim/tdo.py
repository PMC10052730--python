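"""Tasmanian Devil Optimization (TDO) for continuous minimization.

TDO alternates two feeding behaviours per candidate ("devil") per
iteration: a carrion phase (exploration), where the devil moves relative
to a randomly chosen population member, and a prey phase (exploitation),
which performs the same guided move followed by a shrinking multiplicative
local search around the current position.  Every proposed move is accepted
greedily, only when it strictly improves fitness, so the population best
is monotone and the trace never degrades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Bounds,
    ObjectiveFunction,
    OptResult,
    as_generator,
    initialize_population,
)

__all__ = [
    "TDOConfig",
    "select_random_other",
    "guided_move",
    "local_search_radius",
    "local_search_move",
    "tdo_minimize",
]


@dataclass
class TDOConfig:
    """Settings for :func:`tdo_minimize`.

    ``p_explore`` is the per-devil, per-iteration probability of taking
    the carrion (exploration) branch instead of the prey (exploitation)
    branch; the intensity factor I of the guided move is drawn fresh per
    move, uniformly from {1, 2}.
    """

    pop_size: int = 30
    iterations: int = 100
    p_explore: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError(
                "invalid configuration: TDO needs pop_size >= 2 "
                "(guided moves require a second population member)"
            )
        if self.iterations < 1:
            raise ValueError("invalid configuration: iterations must be >= 1")
        if not 0.0 <= self.p_explore <= 1.0:
            raise ValueError("invalid configuration: p_explore must lie in [0, 1]")


def select_random_other(j: int, pop_size: int, rng: np.random.Generator) -> int:
    """Index of a population member chosen uniformly from all rows except ``j``."""
    if pop_size < 2:
        raise ValueError("invalid configuration: pop_size must be >= 2")
    if not 0 <= j < pop_size:
        raise ValueError(f"index {j} out of range for population of {pop_size}")
    i = int(rng.integers(pop_size - 1))
    return i if i < j else i + 1


def guided_move(
    x: np.ndarray,
    target: np.ndarray,
    f_x: float,
    f_target: float,
    intensity: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move ``x`` toward a fitter target, or away from a worse one.

    Per dimension k with independent S ~ U[0, 1]:

    * ``f_target < f_x``  ->  ``x_k + S * (target_k - I * x_k)``
    * otherwise           ->  ``x_k + S * (x_k - target_k)``

    where I is the intensity factor (1 or 2).
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if x.shape != target.shape:
        raise ValueError("position and target must have the same shape")
    s = rng.random(x.shape)
    if f_target < f_x:
        return x + s * (target - intensity * x)
    return x + s * (x - target)


def local_search_radius(t: int, iterations: int) -> float:
    """Shrinking neighbourhood radius ``s = 0.01 * (1 - t / T)``.

    Starts at 0.01 and vanishes at the final iteration so late moves only
    refine locally.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0 <= t <= iterations:
        raise ValueError(f"iteration index {t} outside [0, {iterations}]")
    return 0.01 * (1.0 - t / iterations)


def local_search_move(
    x: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative perturbation: each coordinate moves within
    ``+- radius * |x_k|`` (so the origin is a fixed point)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    x = np.asarray(x, dtype=float)
    r = rng.random(x.shape)
    return x + (2.0 * r - 1.0) * radius * x


def tdo_minimize(
    objective: ObjectiveFunction,
    bounds: Bounds,
    config: TDOConfig | None = None,
    *,
    max_evaluations: int | None = None,
) -> OptResult:
    """Run TDO on ``objective`` inside ``bounds``.

    Out-of-bounds proposals are clamped to the box before evaluation.
    ``max_evaluations`` (when given) caps the total number of objective
    calls, including the initial population, so benchmark harnesses can
    equalize budgets across algorithms; the run stops as soon as the
    budget is exhausted.
    """
    config = config or TDOConfig()
    rng = as_generator(config.seed)

    pop = initialize_population(objective, bounds, config.pop_size, rng)
    n_evals = pop.size
    best = pop.best_index()
    best_pos = pop.positions[best].copy()
    best_fit = float(pop.fitness[best])
    trace: list[float] = []

    budget_left = (
        None if max_evaluations is None else max(0, max_evaluations - n_evals)
    )

    def try_accept(j: int, candidate: np.ndarray) -> bool:
        """Evaluate a clamped candidate and accept it if strictly better."""
        nonlocal n_evals, best_pos, best_fit, budget_left
        candidate = bounds.clip(candidate)
        f = float(objective(candidate))
        n_evals += 1
        if budget_left is not None:
            budget_left -= 1
        if f < pop.fitness[j]:
            pop.positions[j] = candidate
            pop.fitness[j] = f
            if f < best_fit:
                best_fit = f
                best_pos = candidate.copy()
            return True
        return False

    exhausted = False
    T = config.iterations
    for t in range(1, T + 1):
        for j in range(pop.size):
            if budget_left is not None and budget_left <= 0:
                exhausted = True
                break
            x = pop.positions[j]
            if rng.random() < config.p_explore:
                # carrion phase: guided move relative to a random other devil
                i = select_random_other(j, pop.size, rng)
                intensity = int(rng.integers(1, 3))
                cand = guided_move(
                    x, pop.positions[i], pop.fitness[j], pop.fitness[i], intensity, rng
                )
                try_accept(j, cand)
            else:
                # prey phase: guided move, then shrinking local search
                i = select_random_other(j, pop.size, rng)
                intensity = int(rng.integers(1, 3))
                cand = guided_move(
                    x, pop.positions[i], pop.fitness[j], pop.fitness[i], intensity, rng
                )
                try_accept(j, cand)
                if budget_left is not None and budget_left <= 0:
                    exhausted = True
                    break
                radius = local_search_radius(t, T)
                try_accept(j, local_search_move(pop.positions[j], radius, rng))
        trace.append(best_fit)
        if exhausted:
            break

    return OptResult(
        best_position=best_pos,
        best_fitness=best_fit,
        trace=np.asarray(trace),
        iterations=len(trace),
        n_evaluations=n_evals,
        seed=config.seed,
    )
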