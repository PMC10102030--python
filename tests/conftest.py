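import numpy as np
import pytest

from etcfit.fba import ECModel, Enzyme, GrowthCondition, Reaction
from etcfit.fitness import Evaluator
from etcfit.particles import Particle
from etcfit.synthetic import SyntheticScenario, default_prior, make_scenario


@pytest.fixture(scope="session")
def scenario_bundle():
    """Default synthetic study system (6 enzymes, 2% noise, seed 1)."""
    model, truth, datasets = make_scenario(seed=1)
    scenario = SyntheticScenario(seed=1)
    evaluator = Evaluator(model, datasets, ratelaw=scenario.ratelaw,
                          ngam=scenario.ngam, withhold_chemostat=True)
    return {"model": model, "truth": truth, "datasets": datasets,
            "scenario": scenario, "evaluator": evaluator,
            "prior": default_prior(model)}


@pytest.fixture(scope="session")
def noise_free_bundle():
    model, truth, datasets = make_scenario(seed=1, noise_sigma=0.0)
    scenario = SyntheticScenario(seed=1, noise_sigma=0.0)
    evaluator = Evaluator(model, datasets, ratelaw=scenario.ratelaw,
                          ngam=scenario.ngam)
    return {"model": model, "truth": truth, "datasets": datasets,
            "scenario": scenario, "evaluator": evaluator}


def chain_model(enzyme_capacity: float | None = None) -> ECModel:
    """Linear chain: uptake(<=10) -> A -> B -> C -> sink(=biomass).

    With ``enzyme_capacity`` set, one enzyme limits the A->B step to that
    flux (kcat * 3600 * pool / mw = capacity).
    """
    enzymes = []
    if enzyme_capacity is not None:
        enzymes = [Enzyme("E1", mw=1.0, kcat_ref=enzyme_capacity / 3600.0,
                          reactions=["R1"])]
    model = ECModel(
        metabolites=["A", "B", "C"],
        reactions=[
            Reaction("UPT", {"A": 1.0}, 0.0, 10.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 1000.0),
            Reaction("BIO", {"C": -1.0}, 0.0, 1000.0),
        ],
        enzymes=enzymes,
        pool=1.0,
        biomass_rxn="BIO",
        exchanges={"glucose": "UPT"},
    )
    model.validate()
    return model


def empty_particle(model: ECModel) -> Particle:
    return Particle(model.enzyme_ids, np.zeros(3 * len(model.enzymes)))


@pytest.fixture
def batch_condition():
    return GrowthCondition("t", 303.15, "aerobic-batch", ngam=0.0)
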