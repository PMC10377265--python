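"""Advanced Al-Biruni Earth Radius (ABER) metaheuristic.

BER is a population method whose exploration step size descends from
Al-Biruni's trigonometric estimate of the Earth's radius,

    r = h * cos(x) / (1 - cos(x)),

with h ~ U(0, 2) and a dip angle x drawn in degrees. The advanced variant
adds, on top of plain BER:

* dynamic group sizing — the exploration share of the population shrinks
  linearly from 70% to 30% of the population over the run while the
  exploitation share grows correspondingly, with membership reshuffled
  every iteration;
* elitism — the best-so-far solution (the leader, P*) is only ever
  replaced by a strictly better one, so the best-fitness history is
  monotone non-increasing;
* a leader-neighbourhood probe P' = r1 .* (P* + k) whose radius
  k = 1 + 2 t^2 / T^2 grows from 1 to 3 over the run, compared against the
  exploitation move and the better of the two kept;
* stagnation-triggered mutation: a member whose fitness has not improved
  for ``stagnation_limit`` consecutive iterations is, with probability
  ``mutation_probability``, replaced by clip(k + (P1+P2+P3) * exp(-z k))
  built from three distinct peers.

``classic_mode=True`` disables all four additions, leaving baseline BER
(fixed 70/30 groups, no probe, no mutation; elitism bookkeeping of the
returned best is retained so a best solution can be reported).

Minimization convention throughout; classification fitness is
1 - accuracy. Moves are elementwise on positions, which are clipped to the
box bounds after every operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Solution",
    "StepDraws",
    "OptimizerConfig",
    "earth_radius_coefficient",
    "explore_move",
    "exploit_move",
    "elitism_radius",
    "around_leader",
    "mutate",
    "group_sizes",
    "run",
    "multi_run",
    "random_search_baseline",
]

X_MIN_DEGREES = 10.0  # keeps 1 - cos(x) bounded away from 0


@dataclass
class Solution:
    position: np.ndarray
    fitness: float = math.inf
    stagnation_counter: int = 0

    def copy(self) -> "Solution":
        return Solution(self.position.copy(), self.fitness, self.stagnation_counter)


@dataclass
class StepDraws:
    """One member-iteration's random draws (see module docstring)."""

    h: float
    x: float  # degrees
    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray
    z: float

    @classmethod
    def sample(cls, rng: np.random.Generator, dim: int) -> "StepDraws":
        return cls(
            h=float(rng.uniform(0.0, 2.0)),
            x=float(rng.uniform(X_MIN_DEGREES, 180.0)),
            r1=rng.uniform(0.0, 1.0, dim),
            r2=rng.uniform(0.0, 1.0, dim),
            r3=rng.uniform(0.0, 1.0, dim),
            z=float(rng.uniform(0.0, 1.0)),
        )


@dataclass(frozen=True)
class OptimizerConfig:
    population_size: int = 30
    max_iterations: int = 500
    n_runs: int = 30
    exploration_fraction_start: float = 0.70
    exploration_fraction_end: float = 0.30
    mutation_probability: float = 0.5
    stagnation_limit: int = 2
    classic_mode: bool = False
    leader_step_variant: bool = False  # use D = r3.*(P* - P) as the exploit move
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (mutation needs 3 peers)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for f in (self.exploration_fraction_start, self.exploration_fraction_end):
            if not (0.0 < f < 1.0):
                raise ValueError("exploration fractions must lie in (0, 1)")
        if not (0.0 <= self.mutation_probability <= 1.0):
            raise ValueError("mutation_probability must lie in [0, 1]")
        if self.stagnation_limit < 1:
            raise ValueError("stagnation_limit must be >= 1")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must satisfy lower < upper")


def earth_radius_coefficient(draws: StepDraws) -> float:
    """r = h cos(x) / (1 - cos(x)), x in degrees; negative for x > 90."""
    if draws.x <= 0.0:
        raise ValueError(f"dip angle must be positive, got {draws.x}")
    c = math.cos(math.radians(draws.x))
    if abs(1.0 - c) < 1e-12:
        raise ValueError(f"cos(x) = 1 at x = {draws.x}; coefficient undefined")
    return draws.h * c / (1.0 - c)


def _clip(p: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(p, bounds[0], bounds[1])


def explore_move(
    p: np.ndarray, draws: StepDraws, bounds: tuple[float, float]
) -> np.ndarray:
    """Diversification step P + D .* (2 r2 - 1) with D = c .* (P - 1).

    The coefficient vector is c = clip(|r|, 0, 1) * r1, binding the
    earth-radius coefficient r to the step so that small dip angles (large
    |r|) give full-width wandering and angles near 90 degrees freeze the
    member.
    """
    r = earth_radius_coefficient(draws)
    c = min(abs(r), 1.0) * draws.r1
    d = c * (p - 1.0)
    return _clip(p + d * (2.0 * draws.r2 - 1.0), bounds)


def exploit_move(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    leader: np.ndarray,
    draws: StepDraws,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Intensification step r1.*P1 + z r2.*(P2-P3) + (1-z) r3.*(P*-P1)."""
    cand = (
        draws.r1 * p1
        + draws.z * draws.r2 * (p2 - p3)
        + (1.0 - draws.z) * draws.r3 * (leader - p1)
    )
    return _clip(cand, bounds)


def elitism_radius(t: int, max_iterations: int) -> float:
    """k = 1 + 2 t^2 / T^2, growing from 1 (t=0) to 3 (t=T)."""
    return 1.0 + 2.0 * (t * t) / (max_iterations * max_iterations)


def around_leader(
    leader: np.ndarray, k: float, draws: StepDraws, bounds: tuple[float, float]
) -> np.ndarray:
    """Leader-neighbourhood probe P' = r1 .* (P* + k), clipped."""
    return _clip(draws.r1 * (leader + k), bounds)


def mutate(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    k: float,
    z: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Stagnation restart clip(k + (P1 + P2 + P3) e^{-z k})."""
    return _clip(k + (p1 + p2 + p3) * math.exp(-z * k), bounds)


def group_sizes(
    t: int, max_iterations: int, population_size: int, cfg: OptimizerConfig | None = None
) -> tuple[int, int]:
    """(n_explore, n_exploit) under the linear 70% -> 30% schedule.

    n_explore uses round-half-even; n_exploit absorbs the remainder. In
    classic mode the split is frozen at the starting fractions.
    """
    cfg = cfg or OptimizerConfig()
    if cfg.classic_mode:
        frac = cfg.exploration_fraction_start
    else:
        s, e = cfg.exploration_fraction_start, cfg.exploration_fraction_end
        frac = s + (e - s) * (t / max_iterations)
    n_explore = int(np.round(frac * population_size))
    n_explore = min(max(n_explore, 1), population_size - 1)
    return n_explore, population_size - n_explore


def _evaluate(objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if not math.isfinite(value):
        raise ValueError(f"objective returned non-finite value at {position}")
    return value


def run(
    objective,
    config: OptimizerConfig,
    dimension: int,
    rng: np.random.Generator | None = None,
) -> tuple[Solution, list[float]]:
    """One optimization run; returns (best solution, per-iteration history).

    The trajectory is a pure function of (seed, config, objective). History
    entry t is the leader fitness after iteration t+1 and is monotone
    non-increasing by elitism.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.bounds
    pop = [
        Solution(position=rng.uniform(lo, hi, dimension)) for _ in range(config.population_size)
    ]
    for sol in pop:
        sol.fitness = _evaluate(objective, sol.position)
    leader = min(pop, key=lambda s: s.fitness).copy()

    history: list[float] = []
    n = config.population_size
    for t in range(1, config.max_iterations + 1):
        k = elitism_radius(t, config.max_iterations)
        n_explore, _ = group_sizes(t, config.max_iterations, n, config)
        order = rng.permutation(n)  # reshuffled membership each iteration
        explorers = set(order[:n_explore].tolist())
        for i in range(n):
            sol = pop[i]
            draws = StepDraws.sample(rng, dimension)
            old_fitness = sol.fitness
            if i in explorers:
                new_pos = explore_move(sol.position, draws, config.bounds)
                new_fit = _evaluate(objective, new_pos)
                sol.position, sol.fitness = new_pos, new_fit
            else:
                peers = rng.choice([j for j in range(n) if j != i], 3, replace=False)
                p1, p2, p3 = (pop[j].position for j in peers)
                if config.leader_step_variant:
                    # optional leader-step form D = r3 .* (P* - P)
                    cand = _clip(
                        sol.position + draws.r3 * (leader.position - sol.position),
                        config.bounds,
                    )
                else:
                    cand = exploit_move(
                        p1, p2, p3, leader.position, draws, config.bounds
                    )
                cand_fit = _evaluate(objective, cand)
                if not config.classic_mode:
                    probe = around_leader(leader.position, k, draws, config.bounds)
                    probe_fit = _evaluate(objective, probe)
                    if probe_fit < cand_fit:
                        cand, cand_fit = probe, probe_fit
                sol.position, sol.fitness = cand, cand_fit
            # stagnation bookkeeping: strict improvement resets the counter
            if sol.fitness < old_fitness:
                sol.stagnation_counter = 0
            else:
                sol.stagnation_counter += 1
            if (
                not config.classic_mode
                and sol.stagnation_counter >= config.stagnation_limit
                and rng.uniform() < config.mutation_probability
            ):
                peers = rng.choice([j for j in range(n) if j != i], 3, replace=False)
                p1, p2, p3 = (pop[j].position for j in peers)
                new_pos = mutate(p1, p2, p3, k, draws.z, config.bounds)
                sol.position = new_pos
                sol.fitness = _evaluate(objective, new_pos)
                sol.stagnation_counter = 0
            if sol.fitness < leader.fitness:  # strict: ties keep the leader
                leader = sol.copy()
        history.append(leader.fitness)
    return leader, history


def multi_run(
    objective, config: OptimizerConfig, dimension: int
) -> tuple[Solution, list[list[float]]]:
    """``config.n_runs`` independent restarts; best solution overall wins.

    Restart seeds are spawned from ``config.seed`` so runs are independent
    but jointly reproducible.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    best: Solution | None = None
    histories: list[list[float]] = []
    for ss in seeds:
        sol, hist = run(objective, config, dimension, rng=np.random.default_rng(ss))
        histories.append(hist)
        if best is None or sol.fitness < best.fitness:
            best = sol
    return best, histories


def random_search_baseline(
    objective,
    budget: int,
    bounds: tuple[float, float],
    dimension: int,
    seed: int = 0,
) -> Solution:
    """Best of ``budget`` uniform samples over the box; seeded."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    best = Solution(position=rng.uniform(lo, hi, dimension))
    best.fitness = _evaluate(objective, best.position)
    for _ in range(budget - 1):
        pos = rng.uniform(lo, hi, dimension)
        fit = _evaluate(objective, pos)
        if fit < best.fitness:
            best = Solution(position=pos, fitness=fit)
    return best
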