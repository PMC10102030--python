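"""Post-hoc diagnostics of inference runs.

Three views of a run history (or several):

* **FVA over posterior particles** — sample particles above the fitness
  threshold, run flux variability analysis per batch condition, convert the
  per-reaction (min, max) into midpoint and range, and aggregate over
  particles (mean/min/max per simulation × dataset × temperature ×
  reaction).
* **PCA ordination** — standardize the parameter matrix (population
  standard deviation across all particles present in the ordination; the
  same axes serve every panel, so panels are directly comparable) and
  project with scikit-learn's PCA.
* **Single-linkage hierarchical clustering** — pairwise Euclidean distances
  on the same standardized matrix, merged with minimum linkage to emphasize
  discontinuities between clusters; leaves carry the simulation of origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .fba import ECModel, GrowthCondition, TemperatureLP, flux_variability, \
    solve_max_growth
from .fitness import CELSIUS_OFFSET, Dataset, Evaluator
from .history import Individual, RunHistory
from .particles import Particle


def select_fva_particles(history: RunHistory, threshold: float, n: int,
                         rng: np.random.Generator) -> list[Individual]:
    """Uniform sample (without replacement) of up to n particles above the
    fitness threshold.  Raises when no particle qualifies."""
    qualifying = history.posterior(threshold)
    if not qualifying:
        raise ValueError(
            f"no particles with overall R² > {threshold} in this history"
        )
    k = min(n, len(qualifying))
    idx = rng.choice(len(qualifying), size=k, replace=False)
    return [qualifying[i] for i in sorted(idx)]


def fva_midpoint_range(min_flux: float, max_flux: float
                       ) -> tuple[float, float]:
    """Flux midpoint (average of max and min) and range (absolute difference)."""
    if not (np.isfinite(min_flux) and np.isfinite(max_flux)):
        raise ValueError("non-finite FVA bounds must be removed upstream")
    return (min_flux + max_flux) / 2.0, abs(max_flux - min_flux)


def run_fva(model: ECModel, particles: Sequence[Particle],
            datasets: Sequence[Dataset], evaluator: Evaluator,
            simulation_id: str = "run") -> pd.DataFrame:
    """FVA for each particle × batch dataset × temperature.

    Growth is first maximized, then its lower bound locked at the optimum
    before scanning each reaction.  Rows with non-finite bounds (failed
    subproblems) are dropped, mirroring the removal of missing/infinite
    results.  Chemostat datasets are not scanned.
    """
    rows = []
    for ds in datasets:
        if ds.regime == "chemostat":
            continue
        for particle in particles:
            for cond in evaluator.conditions(ds):
                lp = TemperatureLP(model, particle, cond, evaluator.ratelaw)
                sol = solve_max_growth(lp)
                if not sol.optimal:
                    continue
                ranges = flux_variability(lp, sol.objective)
                for rid, (vmin, vmax) in ranges.items():
                    if not (np.isfinite(vmin) and np.isfinite(vmax)):
                        continue
                    mid, rng_ = fva_midpoint_range(vmin, vmax)
                    rows.append({
                        "simulation_id": simulation_id,
                        "particle_id": particle.particle_id,
                        "dataset": ds.name,
                        "temperature_C": cond.temperature - CELSIUS_OFFSET,
                        "reaction_id": rid,
                        "flux_min": vmin, "flux_max": vmax,
                        "midpoint": mid, "range": rng_,
                    })
    return pd.DataFrame(rows)


def aggregate_fva(fva: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of midpoints and ranges per (simulation, dataset,
    temperature, reaction), with the count of contributing particles."""
    keys = ["simulation_id", "dataset", "temperature_C", "reaction_id"]
    grouped = fva.groupby(keys)
    agg = grouped.agg(
        midpoint_mean=("midpoint", "mean"),
        midpoint_min=("midpoint", "min"),
        midpoint_max=("midpoint", "max"),
        range_mean=("range", "mean"),
        range_min=("range", "min"),
        range_max=("range", "max"),
        n_particles=("particle_id", "nunique"),
    ).reset_index()
    return agg


def _standardize(matrix: np.ndarray, names: Sequence[str]
                 ) -> tuple[np.ndarray, list[str]]:
    """Standardize columns by mean / population std; drop constant columns."""
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(
            f"dropping constant parameters from standardization: {dropped}"
        )
    if not keep.any():
        raise ValueError("all parameters are constant; nothing to ordinate")
    z = (matrix[:, keep] - mean[keep]) / std[keep]
    return z, [n for n, k in zip(names, keep) if k]


@dataclass
class Ordination:
    coordinates: pd.DataFrame       # columns PC1..PCk + particle_id + simulation_id
    explained_variance_ratio: np.ndarray
    components: np.ndarray          # orthonormal principal axes (k, p)
    columns: list[str]              # parameter names after constant-drop


def pca_ordination(individuals: Sequence[Individual],
                   param_names: Sequence[str],
                   simulation_ids: Sequence[str] | None = None,
                   n_components: int | None = None) -> Ordination:
    """PCA of the standardized parameter matrix of the given particles.

    Standardization statistics come from *all* particles passed in, so
    plotting subsets of the same ordination keeps panels comparable.
    """
    if len(individuals) < 3:
        raise ValueError("ordination needs at least 3 particles")
    matrix = np.stack([ind.values for ind in individuals])
    z, kept = _standardize(matrix, param_names)
    k = n_components or min(z.shape)
    k = min(k, *z.shape)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(z)
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "particle_id", [ind.particle_id for ind in individuals])
    if simulation_ids is not None:
        df.insert(1, "simulation_id", list(simulation_ids))
    return Ordination(coordinates=df,
                      explained_variance_ratio=pca.explained_variance_ratio_,
                      components=pca.components_,
                      columns=kept)


@dataclass
class DendrogramResult:
    merges: np.ndarray              # scipy linkage matrix (n-1, 4)
    leaf_ids: list[str]
    leaf_simulations: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def single_linkage_tree(individuals: Sequence[Individual],
                        param_names: Sequence[str],
                        simulation_ids: Sequence[str] | None = None
                        ) -> DendrogramResult:
    """Single-linkage dendrogram on standardized Euclidean distances.

    Inputs are sorted by particle id first so tie-prone merge orders are
    reproducible.  Leaf labels keep the simulation of origin so branches can
    be attributed to (or shared between) simulations.
    """
    if len(individuals) < 2:
        raise ValueError("clustering needs at least 2 particles")
    sims = list(simulation_ids) if simulation_ids is not None \
        else ["" for _ in individuals]
    order = sorted(range(len(individuals)),
                   key=lambda i: individuals[i].particle_id)
    individuals = [individuals[i] for i in order]
    sims = [sims[i] for i in order]
    matrix = np.stack([ind.values for ind in individuals])
    z, _ = _standardize(matrix, param_names)
    merges = linkage(pdist(z, metric="euclidean"), method="single")
    return DendrogramResult(merges=merges,
                            leaf_ids=[ind.particle_id for ind in individuals],
                            leaf_simulations=sims)
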