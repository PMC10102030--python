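"""Particle scoring against growth-condition datasets.

For each batch dataset (aerobic / anaerobic) the model is instantiated at
every measured temperature and solved for maximal growth; the predicted
growth rates are compared to the measured ones via the coefficient of
determination R².  For the chemostat dataset the three-stage lexicographic
solve predicts the glucose / ethanol / CO2 exchange fluxes, and all
(observed, predicted) pairs across temperatures and observables pool into a
single R².  The particle's overall fitness is the arithmetic mean of the
per-dataset R² values; withholding the chemostat dataset simply averages
over the remaining two.

R² here is ``1 - SS_res / SS_tot`` about the observed mean, which can be
arbitrarily negative for bad fits — the inference engines only need a total
order, and a score bounded above by 1.

An infeasible LP contributes a predicted value of 0 for its observable
("no growth / no flux") so that every particle receives a defined score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fba import ECModel, GrowthCondition, TemperatureLP, solve_chemostat, \
    solve_max_growth
from .particles import FitnessBreakdown, Particle
from .ratelaw import RateLawConfig

CELSIUS_OFFSET = 273.15

GROWTH_RATE = "growth_rate"
CHEMO_OBSERVABLES = ("glucose_uptake", "ethanol_flux", "co2_flux")

_REGIMES = {"aerobic": "aerobic-batch", "anaerobic": "anaerobic-batch",
            "chemostat": "chemostat"}


@dataclass
class NGAMTable:
    """Non-growth-associated ATP maintenance vs temperature.

    Piecewise-linear in °C; a single point means a constant NGAM.  Units:
    mmol ATP/gDW/h.
    """

    points: list[tuple[float, float]] = field(
        default_factory=lambda: [(25.0, 1.0)])

    def at(self, temperature_C: float) -> float:
        ts = np.array([p[0] for p in self.points], float)
        vs = np.array([p[1] for p in self.points], float)
        order = np.argsort(ts)
        return float(np.interp(temperature_C, ts[order], vs[order]))


@dataclass
class Dataset:
    """Temperature-indexed observations for one cultivation regime.

    ``observations`` has columns (temperature_C, observable, value); batch
    regimes carry one growth-rate row per temperature, the chemostat regime
    carries the three exchange-flux observables per temperature.
    """

    name: str                       # aerobic | anaerobic | chemostat
    observations: pd.DataFrame
    dilution: float | None = None   # 1/h, chemostat only

    def __post_init__(self) -> None:
        if self.name not in _REGIMES:
            raise ValueError(f"unknown dataset name {self.name!r}")
        needed = {"temperature_C", "observable", "value"}
        if not needed <= set(self.observations.columns):
            raise ValueError(f"dataset columns must include {needed}")
        if len(self.observations) < 2:
            raise ValueError("a dataset needs at least 2 observations for R²")
        dup = self.observations.duplicated(["temperature_C", "observable"])
        if dup.any():
            raise ValueError("duplicate (temperature, observable) rows")
        if (self.name == "chemostat") != (self.dilution is not None):
            raise ValueError("dilution must be given iff dataset is chemostat")

    @property
    def regime(self) -> str:
        return _REGIMES[self.name]

    @property
    def temperatures_C(self) -> np.ndarray:
        return np.array(sorted(self.observations["temperature_C"].unique()))

    def to_frame(self) -> pd.DataFrame:
        df = self.observations.copy()
        df.insert(0, "dataset", self.name)
        unit = {"growth_rate": "1/h"}
        df["unit"] = [unit.get(o, "mmol/gDW/h") for o in df["observable"]]
        if self.dilution is not None:
            df["dilution_per_h"] = self.dilution
        return df

    @classmethod
    def list_from_frame(cls, df: pd.DataFrame) -> list["Dataset"]:
        out = []
        for name, grp in df.groupby("dataset", sort=False):
            dilution = None
            if "dilution_per_h" in grp.columns and grp["dilution_per_h"].notna().any():
                dilution = float(grp["dilution_per_h"].iloc[0])
            out.append(cls(str(name),
                           grp[["temperature_C", "observable", "value"]]
                           .reset_index(drop=True),
                           dilution=dilution))
        return out


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (≤ 1, unbounded below)."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length observation/prediction vectors (n >= 2)")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R² undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


class Evaluator:
    """The black-box fitness function: particle -> FitnessBreakdown.

    Bound to one model, one dataset collection and one rate-law config;
    deterministic (repeated evaluation of the same particle returns an
    identical breakdown).
    """

    def __init__(self, model: ECModel, datasets: Sequence[Dataset],
                 ratelaw: RateLawConfig | None = None,
                 ngam: NGAMTable | None = None,
                 withhold_chemostat: bool = False):
        if not datasets:
            raise ValueError("at least one dataset required")
        self.model = model
        self.ratelaw = ratelaw or RateLawConfig()
        self.ngam = ngam or NGAMTable()
        self.datasets = [d for d in datasets
                         if not (withhold_chemostat and d.name == "chemostat")]
        if not self.datasets:
            raise ValueError("withholding chemostat left no datasets")
        self.enzyme_ids = model.enzyme_ids

    def conditions(self, dataset: Dataset) -> list[GrowthCondition]:
        conds = []
        for t_c in dataset.temperatures_C:
            conds.append(GrowthCondition(
                label=f"{dataset.name}@{t_c:g}C",
                temperature=t_c + CELSIUS_OFFSET,
                regime=dataset.regime,
                dilution=dataset.dilution,
                ngam=self.ngam.at(t_c),
            ))
        return conds

    def predict(self, particle: Particle, dataset: Dataset) -> pd.DataFrame:
        """Predicted values aligned to the dataset's observation rows."""
        rows = []
        for cond, t_c in zip(self.conditions(dataset), dataset.temperatures_C):
            lp = TemperatureLP(self.model, particle, cond, self.ratelaw)
            if dataset.regime == "chemostat":
                sol = solve_chemostat(lp, dataset.dilution)
                if sol.optimal:
                    ex = self.model.exchanges
                    pred = {
                        "glucose_uptake": sol.fluxes[ex["glucose"]],
                        "ethanol_flux": sol.fluxes[ex["ethanol"]],
                        "co2_flux": sol.fluxes[ex["co2"]],
                    }
                else:
                    pred = {k: 0.0 for k in CHEMO_OBSERVABLES}
                for obs, val in pred.items():
                    rows.append({"temperature_C": t_c, "observable": obs,
                                 "predicted": val})
            else:
                sol = solve_max_growth(lp)
                growth = sol.objective if sol.optimal else 0.0
                rows.append({"temperature_C": t_c, "observable": GROWTH_RATE,
                             "predicted": growth})
        return pd.DataFrame(rows)

    def dataset_r2(self, particle: Particle, dataset: Dataset) -> float:
        pred = self.predict(particle, dataset)
        merged = dataset.observations.merge(
            pred, on=["temperature_C", "observable"], how="left")
        if merged["predicted"].isna().any():
            missing = merged[merged["predicted"].isna()]
            raise ValueError(
                f"no prediction for observables {set(missing['observable'])}"
            )
        return r_squared(merged["value"].to_numpy(),
                         merged["predicted"].to_numpy())

    def __call__(self, particle: Particle) -> FitnessBreakdown:
        comps = {d.name: self.dataset_r2(particle, d) for d in self.datasets}
        return FitnessBreakdown.from_components(comps)


def evaluate_particle(particle: Particle, model: ECModel,
                      datasets: Sequence[Dataset],
                      ratelaw: RateLawConfig | None = None,
                      ngam: NGAMTable | None = None,
                      withhold_chemostat: bool = False) -> FitnessBreakdown:
    """One-shot convenience wrapper around :class:`Evaluator`."""
    ev = Evaluator(model, datasets, ratelaw=ratelaw, ngam=ngam,
                   withhold_chemostat=withhold_chemostat)
    return ev(particle)
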