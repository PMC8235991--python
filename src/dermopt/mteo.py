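"""Thermal Exchange Optimization (TEO) and its modified variant (MTEO).

TEO is a population metaheuristic in which agents cool toward paired
"environment" agents under an exponential Newton-cooling schedule.  The
modified variant adds opposition-based learning (OBL) and replaces the
uniform random factor of the environmental-temperature decay with a
sinusoidal chaotic map.

The optimizer is a pure box-constrained minimizer: callers maximizing an
objective must negate it.

RNG call order (load-bearing for reproducibility; the unit tests replay it
with an independent transcription):

1. ``initialize``: one ``rng.random((n, d))`` draw for the initial
   positions; if OBL is enabled each member is compared with its opposite
   and the better kept.
2. If chaos is enabled, one draw for the initial chaotic state ``k0``.
3. Each iteration, for each cooling agent in sorted-cost order:
   a. ``m1``, ``m2`` each drawn from {0, 1} (``rng.integers(0, 2)``) unless
      fixed in the config;
   b. the decay factor: ``rng.random()`` in TEO mode, the next chaotic
      iterate in MTEO mode;
   c. component reset: one ``rng.random()`` gate draw, and if it fires,
      ``rng.integers(d)`` for the dimension plus ``rng.random()`` for the
      rewritten value.
   d. if OBL is enabled, the opposite of the updated position is evaluated
      and the better of the pair kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "OptimizerConfig",
    "OptimizeResult",
    "initialize",
    "opposite",
    "chaos_step",
    "env_temperature",
    "update_position",
    "component_reset",
    "optimize",
]

Objective = Callable[[np.ndarray], float]

# Attracting basin of the sinusoidal map for alpha = 2.3.  Iterates that
# fall below CHAOS_FLOOR are drawn toward the absorbing fixed point at 0
# (which would silently disable the chaotic modification), so the stream
# is restarted inside the attractor instead.
CHAOS_FLOOR = 0.45
CHAOS_CEIL = 0.92

# The cooling ratio assumes nonnegative costs; negative ratios (mixed-sign
# objectives) are clamped to 0 and very large ones capped so exp(-gamma*t)
# stays representable.
GAMMA_MAX = 50.0


@dataclass
class Individual:
    """One optimizer agent: a position, its cost and its cooling coefficient."""

    position: np.ndarray
    cost: float
    gamma: float = 0.0


@dataclass
class OptimizerConfig:
    """Run settings for :func:`optimize`.

    ``m1``/``m2`` default to ``None``, meaning each is drawn independently
    from {0, 1} per agent per iteration; a float fixes the value.
    """

    pop_size: int = 100
    max_iter: int = 200
    bounds: tuple[np.ndarray, np.ndarray] | tuple[Sequence[float], Sequence[float]] = ((0.0,), (1.0,))
    pr: float = 0.3
    m1: float | None = None
    m2: float | None = None
    chaos_alpha: float = 2.3
    tm_size: int = 4
    seed: int | None = None
    use_obl: bool = True
    use_chaos: bool = True
    greedy: bool = True

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.bounds[0], dtype=float))
        hi = np.atleast_1d(np.asarray(self.bounds[1], dtype=float))
        if lo.shape != hi.shape:
            raise ValueError("bounds must have matching shapes")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        self.bounds = (lo, hi)
        if self.pop_size < 2 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.pr <= 1.0:
            raise ValueError("pr must lie in [0, 1]")
        if self.tm_size < 0 or self.tm_size > self.pop_size // 2:
            raise ValueError("tm_size must lie in [0, pop_size/2]")

    @property
    def dim(self) -> int:
        return self.bounds[0].size


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_cost: float
    history: np.ndarray
    n_evals: int


def _evaluate(objective: Objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if not math.isfinite(value):
        raise ValueError(f"objective returned non-finite value at {position!r}")
    return value


def opposite(position: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Bound-reflected counterpart: T_max + T_min - T, per component."""
    lo, hi = bounds
    return hi + lo - np.asarray(position, dtype=float)


def chaos_step(k: float, alpha: float = 2.3) -> float:
    """One iterate of the sinusoidal chaotic map alpha * k^2 * sin(pi*k)."""
    return alpha * k * k * math.sin(math.pi * k)


def env_temperature(
    t_env: np.ndarray, t: float, r: float, m1: float, m2: float
) -> np.ndarray:
    """Scaled environmental temperature (1 - (m1 + m2*(1-t))*r) * t_env.

    ``r`` is the stochastic factor: a uniform draw in plain TEO, the next
    chaotic iterate in MTEO.
    """
    return (1.0 - (m1 + m2 * (1.0 - t)) * r) * np.asarray(t_env, dtype=float)


def update_position(
    t_old: np.ndarray,
    t_env: np.ndarray,
    gamma: float,
    t: float,
    bounds: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Newton-cooling update T+ = T_env + (T_old - T_env) exp(-gamma*t), clamped."""
    t_old = np.asarray(t_old, dtype=float)
    t_env = np.asarray(t_env, dtype=float)
    new = t_env + (t_old - t_env) * math.exp(-gamma * t)
    return np.clip(new, bounds[0], bounds[1])


def cooling_coefficient(cost: float, worst_cost: float) -> float:
    """gamma = cost / worst-cost, clamped to [0, GAMMA_MAX].

    A zero worst cost maps to zero (the exchange halts naturally on a
    solved problem); negative ratios, which arise only for mixed-sign
    objectives outside the model's assumptions, are clamped to zero.
    """
    if worst_cost == 0.0:
        return 0.0
    return min(max(cost / worst_cost, 0.0), GAMMA_MAX)


def component_reset(
    position: np.ndarray,
    gamma: float,
    t: float,
    pr: float,
    bounds: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """With probability ``pr`` rewrite one uniformly chosen component.

    The rewritten value is T_min + rnd*(T_max - T_min)*exp(-gamma*t).
    Returns a (possibly new) array; the input is never mutated.
    """
    gate = rng.random()
    if gate >= pr:
        return position
    lo, hi = bounds
    j = int(rng.integers(position.size))
    out = position.copy()
    out[j] = lo[j] + rng.random() * (hi[j] - lo[j]) * math.exp(-gamma * t)
    return out


def _next_chaos(k: float, alpha: float, rng: np.random.Generator) -> float:
    k = chaos_step(k, alpha)
    if k < CHAOS_FLOOR:
        # escaped the chaotic attractor (absorbing fixed point at 0):
        # restart inside the attractor from the seeded stream
        k = CHAOS_FLOOR + rng.random() * (CHAOS_CEIL - CHAOS_FLOOR)
    return k


def initialize(
    objective: Objective,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Random initial population; OBL pairing keeps the better of each pair."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    delta = rng.random((cfg.pop_size, cfg.dim))
    positions = lo + delta * (hi - lo)
    population = []
    for i in range(cfg.pop_size):
        pos = positions[i]
        cost = _evaluate(objective, pos)
        if cfg.use_obl:
            opp = opposite(pos, cfg.bounds)
            opp_cost = _evaluate(objective, opp)
            if opp_cost < cost:
                pos, cost = opp, opp_cost
        population.append(Individual(position=np.array(pos, dtype=float), cost=cost))
    return population


def optimize(objective: Objective, cfg: OptimizerConfig) -> OptimizeResult:
    """Run the full (M)TEO loop and return the best solution found.

    Each iteration the population is sorted by cost, the thermal memory of
    best-ever solutions replaces the current worst members, the best half
    serves as environment for the worst (cooling) half pairwise, and every
    cooling agent is moved by the cooling update, the component reset and
    (in MTEO mode) greedy opposition.
    """
    rng = np.random.default_rng(cfg.seed)
    population = initialize(objective, cfg, rng)
    n_evals = cfg.pop_size * (2 if cfg.use_obl else 1)

    k = rng.random() if cfg.use_chaos else 0.0
    if cfg.use_chaos and k < CHAOS_FLOOR:
        k = CHAOS_FLOOR + rng.random() * (CHAOS_CEIL - CHAOS_FLOOR)

    population.sort(key=lambda ind: ind.cost)
    memory: list[Individual] = [
        Individual(ind.position.copy(), ind.cost) for ind in population[: cfg.tm_size]
    ]
    best = Individual(population[0].position.copy(), population[0].cost)
    history = np.empty(cfg.max_iter)

    half = cfg.pop_size // 2
    for iteration in range(1, cfg.max_iter + 1):
        t = iteration / cfg.max_iter

        # elitist reinjection: best-ever solutions replace the current worst
        population.sort(key=lambda ind: ind.cost)
        for slot, kept in enumerate(memory):
            population[-1 - slot] = Individual(kept.position.copy(), kept.cost)
        population.sort(key=lambda ind: ind.cost)

        worst_cost = population[-1].cost
        for idx in range(half):
            env = population[idx]
            cooling = population[half + idx]
            gamma = cooling_coefficient(cooling.cost, worst_cost)
            cooling.gamma = gamma

            m1 = float(rng.integers(0, 2)) if cfg.m1 is None else cfg.m1
            m2 = float(rng.integers(0, 2)) if cfg.m2 is None else cfg.m2
            if cfg.use_chaos:
                k = _next_chaos(k, cfg.chaos_alpha, rng)
                r = k
            else:
                r = rng.random()

            t_env = env_temperature(env.position, t, r, m1, m2)
            new_pos = update_position(cooling.position, t_env, gamma, t, cfg.bounds)
            new_pos = component_reset(new_pos, gamma, t, cfg.pr, cfg.bounds, rng)

            new_cost = _evaluate(objective, new_pos)
            n_evals += 1
            if cfg.use_obl:
                opp = np.clip(opposite(new_pos, cfg.bounds), *cfg.bounds)
                opp_cost = _evaluate(objective, opp)
                n_evals += 1
                if opp_cost < new_cost:
                    new_pos, new_cost = opp, opp_cost

            # greedy acceptance: without it the component reset keeps
            # reinjecting high-cost agents and the population never settles
            if not cfg.greedy or new_cost < cooling.cost:
                cooling.position = np.array(new_pos, dtype=float)
                cooling.cost = new_cost

        pool = memory + [Individual(i.position.copy(), i.cost) for i in population]
        pool.sort(key=lambda ind: ind.cost)
        memory = pool[: cfg.tm_size]
        if memory and memory[0].cost < best.cost:
            best = Individual(memory[0].position.copy(), memory[0].cost)
        history[iteration - 1] = best.cost

    return OptimizeResult(
        best_position=best.position,
        best_cost=best.cost,
        history=history,
        n_evals=n_evals,
    )
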