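"""Adapter binding priors, constraints and the evaluator for the engines.

The inference engines are agnostic about what a parameter vector means:
they only need prior sampling, constraint repair for proposals, per-update
admissibility checks and an evaluator.  ``ThermalProblem`` supplies those
for thermal-parameter inference on an enzyme-constrained model;
:class:`etcfit.toy.ToyProblem` supplies them for the bimodal benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness import Evaluator
from .history import Individual
from .particles import (ConstraintResampleError, FitnessBreakdown, Particle,
                        PriorSpec, constrain_vector, parameter_names)


@dataclass
class ThermalProblem:
    """Thermal-parameter inference problem over a model's enzyme list."""

    prior: PriorSpec
    evaluator: Evaluator

    def __post_init__(self) -> None:
        if self.prior.enzyme_ids != self.evaluator.enzyme_ids:
            raise ValueError("prior and model enzyme lists differ")
        self.enzyme_ids = self.prior.enzyme_ids
        self.param_names = tuple(parameter_names(self.enzyme_ids))
        self.dim = 3 * len(self.enzyme_ids)

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        values = rng.normal(self.prior.mean, self.prior.std)
        return constrain_vector(values, self.prior.mean, self.prior.std, rng)

    def repair(self, values: np.ndarray, mean: np.ndarray, std: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        return constrain_vector(values, mean, std, rng)

    def update_ok(self, values: np.ndarray, k: int) -> bool:
        """Is the enzyme triple owning parameter k still admissible?"""
        e = k // 3
        tm, topt = values[3 * e], values[3 * e + 1]
        return tm > topt > 0.0

    def evaluate(self, values: np.ndarray) -> FitnessBreakdown:
        return self.evaluator(self.particle(values))

    def particle(self, values: np.ndarray, **kw) -> Particle:
        return Particle(self.enzyme_ids, values, **kw)

    def individual_to_particle(self, ind: Individual) -> Particle:
        return Particle(self.enzyme_ids, ind.values, fitness=ind.fitness,
                        generation=ind.generation, particle_id=ind.particle_id)
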