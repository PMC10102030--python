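"""Sequential-Monte-Carlo approximate Bayesian calculation.

Each iteration fits an independent normal to the current population
(per-parameter mean and population standard deviation), draws a batch of
proposal particles from it (resampling any parameter that breaks the
thermal admissibility constraint), evaluates them, pools proposals with the
incumbents and keeps the best ``population_size`` by overall R²
(truncation selection).  No perturbation-kernel weighting or tolerance
schedule is applied — the method is deliberately the plain
moment-resampling scheme whose mode-collapse pathology the toy benchmark
exposes: on a bimodal landscape the population-moment proposal cannot hold
two separated modes, and truncation selection then bottlenecks the
population onto one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .history import Individual, RunHistory
from .particles import PopulationStats


@dataclass
class ABCConfig:
    """Settings of the SMC-ABC engine.

    Defaults follow the full-scale setup (500 iterations, population 100,
    128 proposals per iteration); the toy benchmark overrides them.
    ``posterior_threshold`` defines the estimated posterior as the
    collection of evaluated particles with overall R² above it.
    """

    iterations: int = 500
    population_size: int = 100
    proposals: int = 128
    seed: int = 0
    posterior_threshold: float = 0.9
    stop_at_fitness: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.proposals < 1:
            raise ValueError("need at least one proposal per iteration")


def _stats(values: np.ndarray) -> PopulationStats:
    return PopulationStats(mean=values.mean(axis=0),
                           std=values.std(axis=0, ddof=0))


def propose_particle(stats: PopulationStats, problem,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one proposal vector from the population moments.

    Parameters are independent Normal(mean_k, σ_k); constraint-violating
    parameters are resampled via the problem's repair hook (which raises
    once its redraw budget is exhausted).
    """
    values = rng.normal(stats.mean, stats.std)
    return problem.repair(values, stats.mean, stats.std, rng)


def abc_iteration(population: list[Individual], problem, cfg: ABCConfig,
                  rng: np.random.Generator, generation: int,
                  id_prefix: str, history: RunHistory | None = None
                  ) -> list[Individual]:
    """One propose/evaluate/truncate step over the pooled candidate set."""
    values = np.stack([ind.values for ind in population])
    stats = _stats(values)
    newcomers = []
    for i in range(cfg.proposals):
        v = propose_particle(stats, problem, rng)
        ind = Individual(f"{id_prefix}-g{generation}-i{i}", generation,
                         v, problem.evaluate(v))
        newcomers.append(ind)
        if history is not None:
            history.records.append(ind)
    pooled = list(population) + newcomers
    # stable sort: ties keep creation order (incumbents first)
    pooled.sort(key=lambda ind: -ind.overall)
    return pooled[: cfg.population_size]


def run_abc(problem, cfg: ABCConfig,
            progress: Callable[[int, float, float], None] | None = None
            ) -> RunHistory:
    """Run the full SMC-ABC loop and return its complete history."""
    rng = np.random.default_rng(cfg.seed)
    prefix = f"abc-s{cfg.seed}"
    history = RunHistory(param_names=list(problem.param_names),
                         meta={"engine": "abc", "seed": cfg.seed,
                               "iterations": cfg.iterations,
                               "population_size": cfg.population_size,
                               "proposals": cfg.proposals,
                               "posterior_threshold": cfg.posterior_threshold})
    population = []
    for i in range(cfg.population_size):
        v = problem.sample_prior(rng)
        ind = Individual(f"{prefix}-g0-prior{i}", 0, v, problem.evaluate(v))
        population.append(ind)
        history.records.append(ind)
    history.populations.append([p.particle_id for p in population])

    for gen in range(1, cfg.iterations + 1):
        population = abc_iteration(population, problem, cfg, rng, gen,
                                   prefix, history)
        history.populations.append([p.particle_id for p in population])
        best = max(p.overall for p in population)
        if progress is not None:
            fitnesses = [p.overall for p in population]
            progress(gen, best, float(np.median(fitnesses)))
        if cfg.stop_at_fitness is not None and best >= cfg.stop_at_fitness:
            break
    history.meta["generations_run"] = len(history.populations) - 1
    return history
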