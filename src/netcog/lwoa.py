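"""Whale optimization algorithm (WOA) and its Levy-flight variant (LWOA).

WOA is a population metaheuristic modeled on humpback hunting. Each
candidate ("whale") position X is updated per iteration by one of three
moves, chosen by a coin flip p and the magnitude of the coefficient H:

* encircling the best-so-far X*:  X <- X* - H * |C*X* - X|      (|H| < 1, p < 0.5)
* random search around a random whale X_rand (exploration)      (|H| >= 1, p < 0.5)
* logarithmic spiral toward X*:  X <- X* + M3 * e^(b*l) cos(2*pi*l)  (p >= 0.5)

with H = 2*h*r1 - h, C = 2*r2, r1/r2/r3 uniform(0,1), and the convergence
factor h shrinking from 2 to 0 over the run (linearly in standard WOA). Once
h <= 1 — past the midpoint of the linear schedule — |H| < 1 always holds and
the swarm can no longer take the random-search branch.

The Levy variant replaces r1 in H by a heavy-tailed Levy-flight draw
(Mantegna's algorithm: s = mu / |nu|^(1/beta), mu ~ N(0, sigma_mu^2),
nu ~ N(0, 1)), restoring the ability to make occasional long jumps out of
local optima late in the run, and switches h to a schedule that decays
slowly early and exponentially late.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "OptimizerConfig",
    "WhaleSwarm",
    "OptimizeResult",
    "linear_h",
    "modified_h",
    "H_SCHEDULES",
    "mantegna_sigma_mu",
    "levy_step",
    "woa_update",
    "optimize",
]


def linear_h(t: float, t_max: int) -> float:
    """Standard WOA convergence factor h = 2 - 2t/T_max."""
    return 2.0 - 2.0 * t / t_max


def modified_h(t: float, t_max: int) -> float:
    """Slow-early / fast-late convergence schedule for the Levy variant.

    h(t) = 2 exp(0.15 - ln(10) * (t/T_max)^4): starts at ~2 e^0.15 = 2.32,
    stays nearly flat through the first half of the run (quartic exponent),
    then drops exponentially toward 2 e^(0.15 - ln 10) ~ 0.23. The printed
    source formula for this schedule is typographically ambiguous; this
    parse is the registry default because it meets the stated behavioral
    contract, and the alternatives below are selectable via
    ``OptimizerConfig.h_schedule``.
    """
    return 2.0 * math.exp(0.15 - math.log(10.0) * (t / t_max) ** 4)


def _modified_h_exp_linear(t: float, t_max: int) -> float:
    """Alternative parse: h(t) = 2 exp(0.15 - ln(10) * t/T_max)."""
    return 2.0 * math.exp(0.15 - math.log(10.0) * (t / t_max))


H_SCHEDULES = {
    "linear": linear_h,
    "modified": modified_h,
    "modified_exp_linear": _modified_h_exp_linear,
}


@dataclass
class OptimizerConfig:
    """Swarm settings; defaults tuned for a 2-D kernel-hyperparameter search."""

    population_size: int = 20
    max_iters: int = 100
    bounds: tuple[tuple[float, float], ...] = ((-10.0, 10.0), (-10.0, 10.0))
    spiral_constant: float = 1.0
    variant: str = "levy"          # "standard" (WOA) or "levy" (LWOA)
    beta: float = 1.5              # Levy stability index
    sigma_mu: float | None = None  # Mantegna scale; None -> closed form
    sigma_nu: float = 1.0
    h_schedule: str | None = None  # None -> linear (standard) / modified (levy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if not 0.0 < self.beta <= 2.0:
            raise ValueError("beta must lie in (0, 2]")
        if self.variant not in ("standard", "levy"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_dim(self) -> int:
        return len(self.bounds)

    def schedule(self):
        if self.h_schedule is not None:
            return H_SCHEDULES[self.h_schedule]
        return H_SCHEDULES["modified" if self.variant == "levy" else "linear"]


@dataclass
class WhaleSwarm:
    """Mutable swarm state: positions, best-so-far and iteration counter."""

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0
    branch_counts: dict = field(
        default_factory=lambda: {"encircle": 0, "search": 0, "spiral": 0})


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration


def mantegna_sigma_mu(beta: float) -> float:
    """Closed-form Mantegna scale for the Levy step numerator.

    sigma_mu = [Gamma(1+beta) sin(pi beta/2) /
                (Gamma((1+beta)/2) beta 2^((beta-1)/2))]^(1/beta);
    0.6966 at the default stability index beta = 1.5.
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = _gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_step(
    beta: float,
    sigma_mu: float,
    rng: np.random.Generator,
    size=None,
    sigma_nu: float = 1.0,
):
    """Heavy-tailed Levy-flight step s = mu / |nu|^(1/beta).

    mu ~ N(0, sigma_mu^2) and nu ~ N(0, sigma_nu^2); |s| has a power-law
    tail P(|s| > c) ~ c^(-beta).
    """
    mu = rng.normal(0.0, sigma_mu, size=size)
    nu = rng.normal(0.0, sigma_nu, size=size)
    return mu / np.abs(nu) ** (1.0 / beta)


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def woa_update(
    swarm: WhaleSwarm,
    config: OptimizerConfig,
    rng: np.random.Generator,
    objective=None,
) -> WhaleSwarm:
    """Advance the swarm one iteration in place (returns the same object).

    Every whale takes exactly one branch (encircle / random search /
    spiral); positions are clipped to the bounds, and when an ``objective``
    is supplied the best-so-far is updated immediately whenever a better
    feasible solution appears.
    """
    t, t_max = swarm.iteration, config.max_iters
    h = config.schedule()(t, t_max)
    h2 = -1.0 - t / t_max
    sigma_mu = (config.sigma_mu if config.sigma_mu is not None
                else mantegna_sigma_mu(config.beta))
    n, d = swarm.positions.shape
    for i in range(n):
        x = swarm.positions[i]
        p = rng.random()
        if config.variant == "levy":
            H = 2.0 * h * levy_step(config.beta, sigma_mu, rng,
                                    sigma_nu=config.sigma_nu) - h
        else:
            H = 2.0 * h * rng.random() - h
        C = 2.0 * rng.random()
        if p < 0.5:
            if abs(H) < 1.0:
                m1 = np.abs(C * swarm.best_position - x)
                new = swarm.best_position - H * m1
                swarm.branch_counts["encircle"] += 1
            else:
                x_rand = swarm.positions[rng.integers(n)]
                m2 = np.abs(C * x_rand - x)
                new = x_rand - H * m2
                swarm.branch_counts["search"] += 1
        else:
            r3 = rng.random()
            l = (h2 - 1.0) * r3 + 1.0
            m3 = np.abs(swarm.best_position - x)
            new = (swarm.best_position
                   + m3 * math.exp(config.spiral_constant * l)
                   * math.cos(2.0 * math.pi * l))
            swarm.branch_counts["spiral"] += 1
        new = _clip_to_bounds(new, config.bounds)
        swarm.positions[i] = new
        if objective is not None:
            f = float(objective(new))
            if not np.isfinite(f):
                # resample an in-bounds position instead of keeping a
                # non-finite candidate
                lo = np.array([b[0] for b in config.bounds])
                hi = np.array([b[1] for b in config.bounds])
                swarm.positions[i] = rng.uniform(lo, hi)
                f = float(objective(swarm.positions[i]))
            swarm.fitness[i] = f
            if np.isfinite(f) and f < swarm.best_fitness:
                swarm.best_fitness = f
                swarm.best_position = swarm.positions[i].copy()
    swarm.iteration += 1
    return swarm


def _init_swarm(objective, config: OptimizerConfig,
                rng: np.random.Generator) -> WhaleSwarm:
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    for _ in range(20):  # bounded retries if the objective is non-finite
        positions = rng.uniform(lo, hi, size=(config.population_size, config.n_dim))
        fitness = np.array([float(objective(x)) for x in positions])
        if np.isfinite(fitness).any():
            break
    else:
        raise RuntimeError("objective non-finite at every sampled position")
    best = int(np.nanargmin(np.where(np.isfinite(fitness), fitness, np.nan)))
    return WhaleSwarm(positions=positions, fitness=fitness,
                      best_position=positions[best].copy(),
                      best_fitness=float(fitness[best]))


def optimize(objective, config: OptimizerConfig) -> OptimizeResult:
    """Minimize ``objective`` over the bounded box; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    swarm = _init_swarm(objective, config, rng)
    trace = np.empty(config.max_iters)
    for t in range(config.max_iters):
        woa_update(swarm, config, rng, objective=objective)
        trace[t] = swarm.best_fitness
    return OptimizeResult(best_position=swarm.best_position,
                          best_fitness=swarm.best_fitness, trace=trace)
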