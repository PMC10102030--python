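"""High-level modelling interface: build once, ``fit()``, inspect results.

``ThermalGEM`` binds an enzyme-constrained model to its growth datasets the
way a statistical model binds to data; ``fit`` runs one of the two
inference engines against a prior and returns a ``ThermalFitResults``
carrying the best particle, the estimated posterior, per-enzyme estimate
tables with posterior spread, and the post-hoc diagnostics (FVA over
posterior particles, PCA ordination, single-linkage dendrogram).

    >>> model = ThermalGEM(ec_model, datasets)            # doctest: +SKIP
    >>> res = model.fit(prior, method="de", seed=1)       # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .de import DEConfig, run_crowding_de
from .diagnostics import DendrogramResult, Ordination, aggregate_fva, \
    pca_ordination, run_fva, select_fva_particles, single_linkage_tree
from .fba import ECModel
from .fitness import Dataset, Evaluator, NGAMTable
from .history import RunHistory
from .particles import PARAM_NAMES, Particle, PriorSpec, FitnessBreakdown
from .problems import ThermalProblem
from .ratelaw import RateLawConfig
from .smc import ABCConfig, run_abc


class ThermalGEM:
    """An enzyme-constrained model bound to its growth-condition data."""

    def __init__(self, ec_model: ECModel, datasets: Sequence[Dataset],
                 ratelaw: RateLawConfig | None = None,
                 ngam: NGAMTable | None = None,
                 withhold_chemostat: bool = False):
        ec_model.validate()
        self.ec_model = ec_model
        self.datasets = list(datasets)
        self.evaluator = Evaluator(ec_model, datasets, ratelaw=ratelaw,
                                   ngam=ngam,
                                   withhold_chemostat=withhold_chemostat)

    @classmethod
    def from_files(cls, model_path, dataset_path, **kw) -> "ThermalGEM":
        from .runio import load_datasets, load_model
        return cls(load_model(model_path), load_datasets(dataset_path), **kw)

    @property
    def enzyme_ids(self) -> tuple[str, ...]:
        return self.ec_model.enzyme_ids

    def evaluate(self, particle: Particle) -> FitnessBreakdown:
        """Score a particle (per-dataset R² and their mean)."""
        return self.evaluator(particle)

    def fit(self, prior: PriorSpec, method: str = "de", seed: int = 0,
            progress=None, **options) -> "ThermalFitResults":
        """Run an inference engine and wrap its history in a results object.

        ``method`` is ``"de"`` (CrowdingDE, the multimodality-preserving
        default) or ``"abc"`` (SMC-ABC with truncation selection).  Extra
        keyword options go into the engine config (population_size,
        generations/iterations, F, CR, ...).
        """
        problem = ThermalProblem(prior, self.evaluator)
        if method == "de":
            cfg = DEConfig(seed=seed, **options)
            history = run_crowding_de(problem, cfg, progress=progress)
        elif method == "abc":
            cfg = ABCConfig(seed=seed, **options)
            history = run_abc(problem, cfg, progress=progress)
        else:
            raise ValueError(f"unknown method {method!r}")
        return ThermalFitResults(self, problem, history,
                                 posterior_threshold=cfg.posterior_threshold)


@dataclass
class ThermalFitResults:
    """Estimates, uncertainties and diagnostics of one inference run."""

    model: ThermalGEM
    problem: ThermalProblem
    history: RunHistory
    posterior_threshold: float

    @property
    def best_particle(self) -> Particle:
        return self.problem.individual_to_particle(self.history.best())

    @property
    def best_fitness(self) -> FitnessBreakdown:
        return self.history.best().fitness

    def posterior_particles(self, threshold: float | None = None
                            ) -> list[Particle]:
        thr = self.posterior_threshold if threshold is None else threshold
        return [self.problem.individual_to_particle(i)
                for i in self.history.posterior(thr)]

    def params_frame(self) -> pd.DataFrame:
        """Per-enzyme best estimate plus posterior mean and spread."""
        best = self.best_particle
        posterior = self.history.posterior(self.posterior_threshold)
        post = np.stack([i.values for i in posterior]) if posterior else None
        rows = []
        for i, eid in enumerate(self.model.enzyme_ids):
            for j, pname in enumerate(PARAM_NAMES):
                k = 3 * i + j
                row = {"enzyme": eid, "param": pname,
                       "estimate": best.values[k]}
                if post is not None:
                    row["posterior_mean"] = post[:, k].mean()
                    row["posterior_sd"] = post[:, k].std(ddof=0)
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        meta = self.history.meta
        fb = self.best_fitness
        lines = [
            "Thermal parameter fit",
            "=" * 60,
            f"engine: {meta.get('engine')}   seed: {meta.get('seed')}   "
            f"generations: {meta.get('generations_run')}",
            f"evaluations: {len(self.history.records)}",
            f"best overall R2: {fb.overall:.4f}   ("
            + ", ".join(f"{k}: {v:.4f}" for k, v in fb.components.items())
            + ")",
            f"posterior (R2 > {self.posterior_threshold}): "
            f"{len(self.history.posterior(self.posterior_threshold))} particles",
            "",
            self.params_frame().to_string(index=False,
                                          float_format=lambda v: f"{v:10.2f}"),
        ]
        return "\n".join(lines)

    # -- diagnostics --------------------------------------------------------

    def fva(self, n_particles: int = 20, threshold: float | None = None,
            seed: int = 0, simulation_id: str = "run"
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """FVA over sampled posterior particles; returns (rows, aggregate)."""
        thr = self.posterior_threshold if threshold is None else threshold
        rng = np.random.default_rng(seed)
        inds = select_fva_particles(self.history, thr, n_particles, rng)
        particles = [self.problem.individual_to_particle(i) for i in inds]
        rows = run_fva(self.model.ec_model, particles, self.model.datasets,
                       self.model.evaluator, simulation_id=simulation_id)
        return rows, aggregate_fva(rows)

    def ordination(self, threshold: float | None = None,
                   include_all: bool = False) -> Ordination:
        thr = self.posterior_threshold if threshold is None else threshold
        inds = (self.history.records if include_all
                else self.history.posterior(thr))
        sims = [self.history.meta.get("engine", "run")] * len(inds)
        return pca_ordination(inds, self.history.param_names,
                              simulation_ids=sims)

    def dendrogram(self, threshold: float | None = None) -> DendrogramResult:
        thr = self.posterior_threshold if threshold is None else threshold
        inds = self.history.posterior(thr)
        sims = [self.history.meta.get("engine", "run")] * len(inds)
        return single_linkage_tree(inds, self.history.param_names,
                                   simulation_ids=sims)

    def convergence(self) -> pd.DataFrame:
        """Best/median/5th/95th-percentile population fitness per generation."""
        return self.history.generation_summary()
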