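"""Geometric binary particle swarm optimization over fixed-length bit masks.

Instead of a velocity update, each particle moves by a three-parent
mask-based crossover (3PMBCX) of its current position, its personal best
and the swarm's global best: per locus a parent is drawn with
probabilities (w1, w2, w3) — non-negative weights summing to one — and
the offspring copies that parent's bit. A bit-flip mutation (default
probability 0.01 per bit) guards against premature convergence.
Personal/global bests update on strict fitness improvement, with exact
ties broken toward the sparser mask (fewer selected features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SwarmConfig", "SwarmResult", "crossover_3pmbcx", "mutate_bitflip", "run_gbpso"]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters.

    ``weights`` are the 3PMBCX parent probabilities (w1 current/inertia,
    w2 personal best/individual, w3 global best/social); they must be
    non-negative and sum to one.
    """

    swarm_size: int = 30
    max_iterations: int = 100
    weights: tuple[float, float, float] = (0.33, 0.34, 0.33)
    mutation_prob: float = 0.01
    seed: int = 0
    patience: int = 20
    init_density: float = 0.5

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        w = self.weights
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError("weights must be three non-negative reals")
        if not math.isclose(sum(w), 1.0, abs_tol=1e-12):
            raise ValueError("weights must sum to 1 (tolerance 1e-12)")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if not 0.0 < self.init_density < 1.0:
            raise ValueError("init_density must lie in (0, 1)")


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    n_iterations: int = 0


def crossover_3pmbcx(
    current: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    weights: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Three-parent mask-based crossover: each offspring bit is copied
    from (current, pbest, gbest) with probabilities (w1, w2, w3)."""
    current = np.asarray(current, dtype=bool)
    pbest = np.asarray(pbest, dtype=bool)
    gbest = np.asarray(gbest, dtype=bool)
    if not (current.shape == pbest.shape == gbest.shape):
        raise ValueError("parent bit vectors must have equal length")
    mask = rng.choice(3, size=current.shape[0], p=np.asarray(weights, dtype=float))
    parents = np.stack([current, pbest, gbest])
    return parents[mask, np.arange(current.shape[0])]


def mutate_bitflip(v: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    v = np.asarray(v, dtype=bool)
    if p == 0.0:
        return v.copy()
    return v ^ (rng.random(v.shape[0]) < p)


def _improves(fitness: float, size: int, best_fitness: float, best_size: int) -> bool:
    # strict improvement, or an exact tie resolved toward fewer genes
    return fitness > best_fitness or (fitness == best_fitness and size < best_size)


def run_gbpso(
    D: int,
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> SwarmResult:
    """Maximize ``fitness`` over {0,1}^D with a geometric binary swarm.

    Positions initialize Bernoulli(init_density) per bit; explicit
    ``initial_positions`` (e.g. a deterministic all-ones seed particle)
    replace the leading random particles. Runs ``max_iterations``
    iterations or stops early after ``patience`` iterations without a
    strict global-best fitness improvement. Deterministic given
    ``config.seed``; the global-best fitness trace is non-decreasing by
    construction.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(config.seed)
    positions = [rng.random(D) < config.init_density for _ in range(config.swarm_size)]
    if initial_positions:
        if len(initial_positions) > config.swarm_size:
            raise ValueError("more injected particles than swarm slots")
        for i, pos in enumerate(initial_positions):
            pos = np.asarray(pos, dtype=bool)
            if pos.shape != (D,):
                raise ValueError("injected particle has wrong length")
            positions[i] = pos.copy()

    def _eval(mask: np.ndarray) -> float:
        value = float(fitness(mask))
        if not math.isfinite(value):
            raise ValueError("fitness returned a non-finite value")
        return value

    fit = [_eval(p) for p in positions]
    pbest = [p.copy() for p in positions]
    pbest_fit = list(fit)
    g = max(
        range(config.swarm_size),
        key=lambda i: (pbest_fit[i], -int(pbest[i].sum())),
    )
    gbest, gbest_fit = pbest[g].copy(), pbest_fit[g]

    trace = [gbest_fit]
    stall = 0
    iterations = 0
    for _ in range(config.max_iterations):
        improved = False
        for i in range(config.swarm_size):
            child = crossover_3pmbcx(positions[i], pbest[i], gbest, config.weights, rng)
            child = mutate_bitflip(child, config.mutation_prob, rng)
            value = _eval(child)
            positions[i] = child
            if _improves(value, int(child.sum()), pbest_fit[i], int(pbest[i].sum())):
                pbest[i], pbest_fit[i] = child.copy(), value
                if _improves(value, int(child.sum()), gbest_fit, int(gbest.sum())):
                    if value > gbest_fit:
                        improved = True
                    gbest, gbest_fit = child.copy(), value
        iterations += 1
        trace.append(gbest_fit)
        stall = 0 if improved else stall + 1
        if stall >= config.patience:
            break
    return SwarmResult(gbest, gbest_fit, trace, iterations)
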