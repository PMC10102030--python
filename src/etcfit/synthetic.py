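"""Synthetic study system: a small etcGEM plus simulated growth datasets.

Stands in for a full yeast-scale enzyme-constrained model and the three
experimental training datasets, reproducing the *structure* of the
inference problem at desk scale: a glucose-fed network with a fermentation
branch (ethanol + CO2), a higher-ATP-yield respiration branch (O2-consuming),
an ATP-coupled biomass reaction and a temperature-adjusted maintenance
(NGAM) flux, with one enzyme per catalyzed reaction drawing on a shared
protein pool.  A known ground-truth particle generates the datasets, so
recovery experiments have an exact reference.

Default dataset shapes follow the experimental regimes being emulated:
growth rates at 8 temperatures spanning 16–42 °C (aerobic batch) and
5–40 °C (anaerobic batch), and glucose/ethanol/CO2 exchange fluxes at 6
temperatures spanning 30–38.5 °C in an aerobic chemostat at dilution
0.1 /h.  Measurement error is multiplicative Gaussian (default σ = 2% of
the value) — growth spans an order of magnitude across the temperature
range, so additive noise would swamp the low-growth points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import ECModel, Enzyme, GrowthCondition, Reaction, TemperatureLP, \
    solve_chemostat, solve_max_growth
from .fitness import CELSIUS_OFFSET, CHEMO_OBSERVABLES, Dataset, GROWTH_RATE, \
    NGAMTable
from .particles import Particle, PriorSpec
from .ratelaw import RateLawConfig


@dataclass
class SyntheticScenario:
    """Knobs of the synthetic study system (defaults ARE the study conditions)."""

    n_enzymes: int = 6
    redundant: bool = False
    noise_sigma: float = 0.02
    seed: int = 0
    aerobic_temps_C: np.ndarray = field(
        default_factory=lambda: np.linspace(16.0, 42.0, 8))
    anaerobic_temps_C: np.ndarray = field(
        default_factory=lambda: np.linspace(5.0, 40.0, 8))
    chemostat_temps_C: np.ndarray = field(
        default_factory=lambda: np.linspace(30.0, 38.5, 6))
    dilution: float = 0.1
    #: maintenance ATP demand rises with temperature (piecewise-linear in °C)
    ngam: NGAMTable = field(default_factory=lambda: NGAMTable(
        points=[(5.0, 0.6), (30.0, 1.0), (42.0, 1.8)]))
    ratelaw: RateLawConfig = field(default_factory=RateLawConfig)

    def __post_init__(self) -> None:
        if self.n_enzymes < 6:
            raise ValueError("the network topology needs at least 6 enzymes")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def build_toy_ecgem(scenario: SyntheticScenario | None = None) -> ECModel:
    """Construct the small enzyme-constrained model.

    Topology: glucose uptake -> glycolysis chain (one or more lumped steps,
    the last yielding pyruvate + ATP) -> fermentation (pyr -> ethanol + CO2)
    or respiration (pyr + 3 O2 -> 3 CO2 + 12 ATP); biomass consumes pyruvate
    and ATP; NGAM burns ATP.  ``n_enzymes`` beyond 6 lengthens the
    glycolysis chain; the redundancy flag duplicates the first glycolysis
    step with its own enzyme, creating a deliberately non-identifiable
    parallel pathway.
    """
    sc = scenario or SyntheticScenario()
    n_glyc = sc.n_enzymes - 5
    chain = ["glc"] + [f"g{i}" for i in range(1, n_glyc)] + ["pyr_pre"]

    metabolites = ["glc", "pyr", "atp", "eth", "co2", "o2"]
    metabolites += [m for m in chain if m not in metabolites and m != "pyr_pre"]

    reactions = [
        Reaction("GLC_UPT", {"glc": 1.0}, 0.0, 10.0),
        Reaction("O2_UPT", {"o2": 1.0}, 0.0, 1000.0),
    ]
    enzymes = [
        Enzyme("E_glc_upt", 100.0, 20.0, ["GLC_UPT"]),
        Enzyme("E_o2_upt", 100.0, 40.0, ["O2_UPT"]),
    ]
    for i in range(n_glyc):
        src = chain[i]
        dst = chain[i + 1]
        rid = f"GLYC{i + 1}" if n_glyc > 1 else "GLYC"
        if dst == "pyr_pre":  # terminal step releases pyruvate + ATP
            stoich = {src: -1.0, "pyr": 2.0, "atp": 2.0}
        else:
            stoich = {src: -1.0, dst: 1.0}
        reactions.append(Reaction(rid, stoich, 0.0, 1000.0))
        enzymes.append(Enzyme(f"E_glyc{i + 1}" if n_glyc > 1 else "E_glyc",
                              100.0, 30.0, [rid]))
    reactions += [
        Reaction("FERM", {"pyr": -1.0, "eth": 1.0, "co2": 1.0}, 0.0, 1000.0),
        Reaction("RESP", {"pyr": -1.0, "o2": -3.0, "co2": 3.0, "atp": 12.0},
                 0.0, 1000.0),
        Reaction("BIOMASS", {"pyr": -1.0, "atp": -10.0}, 0.0, 1000.0),
        Reaction("NGAM", {"atp": -1.0}, 0.0, 1000.0),
        Reaction("ETH_EX", {"eth": -1.0}, 0.0, 1000.0),
        Reaction("CO2_EX", {"co2": -1.0}, 0.0, 1000.0),
    ]
    enzymes += [
        Enzyme("E_ferm", 100.0, 30.0, ["FERM"]),
        Enzyme("E_resp", 100.0, 15.0, ["RESP"]),
        Enzyme("E_bio", 100.0, 5.0, ["BIOMASS"]),
    ]
    if sc.redundant:
        first = reactions[2]
        reactions.append(Reaction(first.id + "_alt", dict(first.stoich),
                                  first.lb, first.ub))
        enzymes.append(Enzyme("E_glyc_alt", 100.0, 30.0, [first.id + "_alt"]))

    model = ECModel(
        metabolites=metabolites,
        reactions=reactions,
        enzymes=enzymes,
        pool=0.02,
        biomass_rxn="BIOMASS",
        exchanges={"glucose": "GLC_UPT", "oxygen": "O2_UPT",
                   "ethanol": "ETH_EX", "co2": "CO2_EX"},
        ngam_rxn="NGAM",
    )
    model.validate()
    return model


def ground_truth_particle(model: ECModel, rng: np.random.Generator) -> Particle:
    """Draw a plausible ground-truth particle for the model's enzymes.

    Topt uniform in 300–320 K, Tm = Topt + 5–20 K, ΔC‡p uniform in
    [-8000, -500] J/(mol·K) — admissible by construction.
    """
    n = len(model.enzymes)
    topt = rng.uniform(300.0, 320.0, n)
    tm = topt + rng.uniform(5.0, 20.0, n)
    dcp = rng.uniform(-8000.0, -500.0, n)
    values = np.column_stack([tm, topt, dcp]).ravel()
    return Particle(model.enzyme_ids, values, particle_id="ground-truth")


def default_prior(model: ECModel) -> PriorSpec:
    """Generic field-plausible prior: N(325, 5²) K for Tm, N(310, 5²) K for
    Topt, N(-3000, 1500²) J/(mol·K) for ΔC‡p, identical across enzymes."""
    return PriorSpec.from_triples(model.enzyme_ids,
                                  (325.0, 310.0, -3000.0),
                                  (5.0, 5.0, 1500.0))


class InfeasibleScenarioError(RuntimeError):
    """The ground truth cannot grow under a requested condition; redraw it."""


def simulate_datasets(model: ECModel, truth: Particle,
                      scenario: SyntheticScenario,
                      rng: np.random.Generator) -> list[Dataset]:
    """Simulate the three datasets from the ground truth, with noise."""

    def noisy(v: float) -> float:
        if scenario.noise_sigma == 0:
            return v
        return v * (1.0 + rng.normal(0.0, scenario.noise_sigma))

    datasets = []
    for name, temps in (("aerobic", scenario.aerobic_temps_C),
                        ("anaerobic", scenario.anaerobic_temps_C)):
        regime = "aerobic-batch" if name == "aerobic" else "anaerobic-batch"
        rows = []
        for t_c in temps:
            cond = GrowthCondition(f"{name}@{t_c:g}C", t_c + CELSIUS_OFFSET,
                                   regime, ngam=scenario.ngam.at(t_c))
            sol = solve_max_growth(
                TemperatureLP(model, truth, cond, scenario.ratelaw))
            if not sol.optimal:
                raise InfeasibleScenarioError(
                    f"ground truth infeasible for {name} at {t_c:g} °C"
                )
            rows.append({"temperature_C": float(t_c),
                         "observable": GROWTH_RATE,
                         "value": noisy(sol.objective)})
        datasets.append(Dataset(name, pd.DataFrame(rows)))

    rows = []
    for t_c in scenario.chemostat_temps_C:
        cond = GrowthCondition(f"chemostat@{t_c:g}C", t_c + CELSIUS_OFFSET,
                               "chemostat", dilution=scenario.dilution,
                               ngam=scenario.ngam.at(t_c))
        sol = solve_chemostat(
            TemperatureLP(model, truth, cond, scenario.ratelaw),
            scenario.dilution)
        if not sol.optimal:
            raise InfeasibleScenarioError(
                f"ground-truth chemostat infeasible at {t_c:g} °C "
                f"(stage {sol.stage_failed})"
            )
        ex = model.exchanges
        for obs, rid in zip(CHEMO_OBSERVABLES,
                            (ex["glucose"], ex["ethanol"], ex["co2"])):
            rows.append({"temperature_C": float(t_c), "observable": obs,
                         "value": noisy(sol.fluxes[rid])})
    datasets.append(Dataset("chemostat", pd.DataFrame(rows),
                            dilution=scenario.dilution))
    return datasets


def make_scenario(seed: int = 0, max_redraws: int = 50,
                  **kw) -> tuple[ECModel, Particle, list[Dataset]]:
    """Build model, ground truth and datasets from one seed.

    A ground-truth draw whose simulated conditions are infeasible (e.g. an
    enzyme too cold-sensitive to cover maintenance at 5 °C) is discarded and
    redrawn from the same stream, so the returned scenario is always
    feasible and still a pure function of the seed.
    """
    scenario = SyntheticScenario(seed=seed, **kw)
    rng = np.random.default_rng(seed)
    model = build_toy_ecgem(scenario)
    for _ in range(max_redraws):
        truth = ground_truth_particle(model, rng)
        try:
            datasets = simulate_datasets(model, truth, scenario, rng)
        except InfeasibleScenarioError:
            continue
        return model, truth, datasets
    raise InfeasibleScenarioError(
        f"no feasible ground truth found in {max_redraws} draws"
    )
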