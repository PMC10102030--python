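"""Candidate parameter sets ("particles") and their priors.

A particle collects, for every enzyme of an enzyme-constrained model, the
three thermal parameters that govern its temperature response:

* ``Tm``   — melting temperature (K), midpoint of thermal denaturation;
* ``Topt`` — temperature optimum (K), where the catalytic rate peaks
  absent denaturation;
* ``dCp``  — activation heat-capacity change ΔC‡p (J/(mol·K)), which sets
  the curvature of the rate–temperature profile.

Physical admissibility requires ``Tm > Topt > 0 K`` for every enzyme.
Particles are stored as flat float vectors of length ``3 × n_enzymes`` in
the fixed order ``(Tm, Topt, dCp)`` per enzyme, following the model's
enzyme list; both inference engines operate on these vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PARAM_NAMES = ("Tm", "Topt", "dCp")

#: redraw budget for constrained prior/proposal sampling, per enzyme
RESAMPLE_BUDGET = 1000


class ConstraintResampleError(RuntimeError):
    """Raised when constrained resampling exhausts its retry budget.

    Signals a prior (or proposal distribution) that is inconsistent with
    the thermal admissibility constraint ``Tm > Topt > 0 K``.
    """


@dataclass(frozen=True)
class EnzymeThermalParams:
    """Thermal parameter triple of a single enzyme."""

    Tm: float
    Topt: float
    dCp: float

    def violations(self) -> list[str]:
        out = []
        if not self.Topt > 0.0:
            out.append("Topt <= 0 K")
        if not self.Tm > self.Topt:
            out.append("Tm <= Topt")
        return out


@dataclass
class FitnessBreakdown:
    """Per-dataset R² components and their arithmetic mean."""

    components: dict[str, float]
    overall: float

    @classmethod
    def from_components(cls, components: dict[str, float]) -> "FitnessBreakdown":
        vals = list(components.values())
        return cls(components=dict(components), overall=float(np.mean(vals)))


@dataclass
class Particle:
    """One candidate parameter set plus bookkeeping metadata.

    ``values`` is the flat vector; ``enzyme_ids`` fixes its interpretation.
    ``particle_id`` records (run seed, generation, creation index) so any
    individual in a run history can be traced to its origin.
    """

    enzyme_ids: tuple[str, ...]
    values: np.ndarray
    fitness: FitnessBreakdown | None = None
    generation: int = 0
    particle_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3 * len(self.enzyme_ids),):
            raise ValueError(
                f"expected {3 * len(self.enzyme_ids)} parameters, "
                f"got {self.values.shape}"
            )

    @property
    def dim(self) -> int:
        return self.values.size

    def enzyme_params(self, enzyme_id: str) -> EnzymeThermalParams:
        i = self.enzyme_ids.index(enzyme_id)
        return EnzymeThermalParams(*self.values[3 * i : 3 * i + 3])

    def iter_enzymes(self) -> Iterable[tuple[str, EnzymeThermalParams]]:
        for i, eid in enumerate(self.enzyme_ids):
            yield eid, EnzymeThermalParams(*self.values[3 * i : 3 * i + 3])

    @property
    def param_names(self) -> list[str]:
        return [f"{eid}__{p}" for eid in self.enzyme_ids for p in PARAM_NAMES]


def parameter_names(enzyme_ids: Sequence[str]) -> list[str]:
    return [f"{eid}__{p}" for eid in enzyme_ids for p in PARAM_NAMES]


@dataclass
class PriorSpec:
    """Independent-normal prior per parameter, indexed like the particle vector."""

    enzyme_ids: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        m = 3 * len(self.enzyme_ids)
        if self.mean.shape != (m,) or self.std.shape != (m,):
            raise ValueError("prior mean/std length must be 3 x n_enzymes")
        if np.any(self.std < 0):
            raise ValueError("prior std must be non-negative")

    @classmethod
    def from_triples(
        cls,
        enzyme_ids: Sequence[str],
        mean_triple: Sequence[float],
        std_triple: Sequence[float],
    ) -> "PriorSpec":
        """Uniform prior: the same (Tm, Topt, dCp) mean/std for all enzymes."""
        n = len(enzyme_ids)
        return cls(
            tuple(enzyme_ids),
            np.tile(np.asarray(mean_triple, float), n),
            np.tile(np.asarray(std_triple, float), n),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, eid in enumerate(self.enzyme_ids):
            for j, p in enumerate(PARAM_NAMES):
                k = 3 * i + j
                rows.append(
                    {"enzyme_id": eid, "param": p,
                     "mean": self.mean[k], "std": self.std[k]}
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriorSpec":
        enzyme_ids = tuple(dict.fromkeys(df["enzyme_id"]))
        mean = np.empty(3 * len(enzyme_ids))
        std = np.empty_like(mean)
        idx = {(r.enzyme_id, r.param): (r.mean, r.std) for r in df.itertuples()}
        for i, eid in enumerate(enzyme_ids):
            for j, p in enumerate(PARAM_NAMES):
                mean[3 * i + j], std[3 * i + j] = idx[(eid, p)]
        return cls(enzyme_ids, mean, std)


@dataclass
class PopulationStats:
    """Per-parameter mean and population-convention standard deviation."""

    mean: np.ndarray
    std: np.ndarray


def check_thermal_constraints(particle: Particle) -> list[tuple[str, str]]:
    """Return (enzyme_id, violation) for every broken inequality; empty if valid."""
    out = []
    for eid, p in particle.iter_enzymes():
        for v in p.violations():
            out.append((eid, v))
    return out


def _triple_valid(tm: float, topt: float) -> bool:
    return tm > topt > 0.0


def constrain_vector(
    values: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    rng: np.random.Generator,
    budget: int = RESAMPLE_BUDGET,
) -> np.ndarray:
    """Redraw parameters of enzymes violating ``Tm > Topt > 0 K``.

    For a ``Topt <= 0`` violation only Topt is redrawn; for ``Tm <= Topt``
    the (Tm, Topt) pair is redrawn jointly, so the procedure terminates
    whenever the distribution assigns positive probability to admissible
    pairs.

    Raises
    ------
    ConstraintResampleError
        if an enzyme stays inadmissible after ``budget`` redraws.
    """
    values = np.array(values, dtype=float)
    n_enz = values.size // 3
    for i in range(n_enz):
        itm, ito = 3 * i, 3 * i + 1
        tries = 0
        while not _triple_valid(values[itm], values[ito]):
            if tries >= budget:
                raise ConstraintResampleError(
                    f"enzyme index {i}: could not satisfy Tm > Topt > 0 K "
                    f"after {budget} redraws (distribution inconsistent "
                    f"with constraint)"
                )
            if not values[ito] > 0.0:
                values[ito] = rng.normal(mean[ito], std[ito])
            else:
                values[itm] = rng.normal(mean[itm], std[itm])
                values[ito] = rng.normal(mean[ito], std[ito])
            tries += 1
    return values


def sample_from_prior(
    prior: PriorSpec,
    rng: np.random.Generator,
    generation: int = 0,
    particle_id: str = "",
) -> Particle:
    """Draw one particle from the prior, enforcing thermal admissibility."""
    values = rng.normal(prior.mean, prior.std)
    values = constrain_vector(values, prior.mean, prior.std, rng)
    return Particle(prior.enzyme_ids, values, generation=generation,
                    particle_id=particle_id)


def permute_prior(prior: PriorSpec, rng: np.random.Generator) -> PriorSpec:
    """Shuffle enzyme labels: each enzyme receives another enzyme's full
    (Tm, Topt, dCp) prior triple.  The multiset of triples is unchanged."""
    n = len(prior.enzyme_ids)
    perm = rng.permutation(n)
    mean = np.empty_like(prior.mean)
    std = np.empty_like(prior.std)
    for new_i, old_i in enumerate(perm):
        mean[3 * new_i : 3 * new_i + 3] = prior.mean[3 * old_i : 3 * old_i + 3]
        std[3 * new_i : 3 * new_i + 3] = prior.std[3 * old_i : 3 * old_i + 3]
    return PriorSpec(prior.enzyme_ids, mean, std)


def population_stats(particles: Sequence[Particle]) -> PopulationStats:
    """Per-parameter mean and standard deviation of a particle population.

    Population convention (divide by n); used consistently for proposal
    generation, crowding distances and post-hoc standardization.
    """
    if len(particles) < 2:
        raise ValueError("population statistics need at least 2 particles")
    mat = np.stack([p.values for p in particles])
    return PopulationStats(mean=mat.mean(axis=0), std=mat.std(axis=0, ddof=0))


def standardized_distance(a: "Particle | np.ndarray", b: "Particle | np.ndarray",
                          stats: PopulationStats) -> float:
    """Euclidean norm of the per-parameter difference scaled by the population
    standard deviation σ_k.  Coordinates with σ_k = 0 contribute nothing (a
    collapsed coordinate carries no discriminating information)."""
    va = a.values if isinstance(a, Particle) else np.asarray(a, float)
    vb = b.values if isinstance(b, Particle) else np.asarray(b, float)
    diff = va - vb
    z = np.where(stats.std > 0, diff / np.where(stats.std > 0, stats.std, 1.0),
                 0.0)
    return float(np.sqrt(np.sum(z * z)))


def population_to_frame(particles: Sequence[Particle]) -> pd.DataFrame:
    """Serialize a particle population: id, generation, R² columns, then one
    column per parameter named ``<enzyme_id>__Tm|Topt|dCp``."""
    comp_keys: list[str] = []
    for p in particles:
        if p.fitness is not None:
            for k in p.fitness.components:
                if k not in comp_keys:
                    comp_keys.append(k)
    rows = []
    for p in particles:
        row: dict[str, object] = {
            "particle_id": p.particle_id,
            "generation": p.generation,
            "R2_overall": p.fitness.overall if p.fitness else np.nan,
        }
        for k in comp_keys:
            row[f"R2_{k}"] = (
                p.fitness.components.get(k, np.nan) if p.fitness else np.nan
            )
        row.update(zip(p.param_names, p.values))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_particles(df: pd.DataFrame) -> list[Particle]:
    """Inverse of :func:`population_to_frame` (full float precision)."""
    param_cols = [c for c in df.columns if "__" in c]
    enzyme_ids = tuple(dict.fromkeys(c.rsplit("__", 1)[0] for c in param_cols))
    ordered = parameter_names(enzyme_ids)
    comp_cols = [c for c in df.columns
                 if c.startswith("R2_") and c != "R2_overall"]
    out = []
    for r in df.itertuples(index=False):
        d = dict(zip(df.columns, r))
        values = np.array([d[c] for c in ordered], float)
        fitness = None
        if not pd.isna(d.get("R2_overall", np.nan)):
            comps = {c[3:]: float(d[c]) for c in comp_cols if not pd.isna(d[c])}
            fitness = FitnessBreakdown(
                components=comps, overall=float(d["R2_overall"])
            )
        out.append(
            Particle(enzyme_ids, values, fitness=fitness,
                     generation=int(d.get("generation", 0)),
                     particle_id=str(d.get("particle_id", "")))
        )
    return out
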