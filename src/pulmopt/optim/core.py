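"""Shared substrate for the population-based optimizers.

Everything in this module follows the minimization convention: smaller
fitness is better, and any maximization use negates its objective before
calling an optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Bounds",
    "Population",
    "OptResult",
    "initialize_population",
    "benchmark_function",
    "sphere",
    "rastrigin",
    "rosenbrock",
    "as_generator",
]

#: An objective maps a position vector of length ``ndim`` to a scalar
#: fitness.  It must be deterministic and finite for in-bounds inputs.
ObjectiveFunction = Callable[[np.ndarray], float]


def as_generator(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` for ``seed``.

    Generators pass through unchanged so that callers can thread one
    stream through several stages.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Bounds:
    """Box constraints: per-dimension lower and upper limits.

    Every dimension must satisfy ``lower[k] < upper[k]`` strictly;
    degenerate (zero-width) boxes are rejected because uniform sampling
    and the optimizers' boundary rules are meaningless on them.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not (lower < upper).all():
            raise ValueError("invalid bounds: require lower < upper in every dimension")

    @classmethod
    def cube(cls, lower: float, upper: float, ndim: int) -> "Bounds":
        """Uniform box ``[lower, upper]^ndim``."""
        return cls(np.full(ndim, float(lower)), np.full(ndim, float(upper)))

    @property
    def ndim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool((x >= self.lower).all() and (x <= self.upper).all())


@dataclass
class Population:
    """Candidate matrix (``pop_size`` rows x ``ndim`` columns) with its
    paired fitness vector.  The fitness entry of a row is re-evaluated by
    the owning algorithm whenever the row changes."""

    positions: np.ndarray
    fitness: np.ndarray

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def best_index(self) -> int:
        return int(np.argmin(self.fitness))


@dataclass
class OptResult:
    """Outcome of one optimizer run.

    ``trace`` holds the best-so-far fitness after each iteration, so it is
    non-increasing by construction (elitism) and its last entry equals
    ``best_fitness``.
    """

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    iterations: int
    n_evaluations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)


def initialize_population(
    objective: ObjectiveFunction,
    bounds: Bounds,
    pop_size: int,
    rng: int | np.random.Generator | None,
) -> Population:
    """Draw ``pop_size`` positions uniformly inside ``bounds`` and evaluate them.

    Each coordinate is independent uniform on ``[lower[k], upper[k]]``;
    the same seed reproduces the matrix bit-for-bit.
    """
    if pop_size < 2:
        raise ValueError("invalid configuration: pop_size must be >= 2")
    gen = as_generator(rng)
    positions = gen.uniform(bounds.lower, bounds.upper, size=(pop_size, bounds.ndim))
    fitness = np.array([objective(row) for row in positions], dtype=float)
    return Population(positions=positions, fitness=fitness)


# --- standard continuous benchmarks (global minimum 0) -----------------------

def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
    )


_BENCHMARKS: dict[str, ObjectiveFunction] = {
    "sphere": sphere,
    "rastrigin": rastrigin,
    "rosenbrock": rosenbrock,
}


def benchmark_function(name: str) -> ObjectiveFunction:
    """Look up a standard benchmark by name (sphere, rastrigin, rosenbrock)."""
    try:
        return _BENCHMARKS[name]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {name!r}; available: {sorted(_BENCHMARKS)}"
        ) from None
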