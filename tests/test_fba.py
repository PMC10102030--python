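import itertools

import numpy as np
import pytest

from conftest import chain_model
from etcfit.fba import (ECModel, Enzyme, GrowthCondition, ModelValidationError,
                        Reaction, TemperatureLP, flux_variability,
                        solve_chemostat, solve_max_growth)
from etcfit.particles import Particle
from etcfit.ratelaw import RateLawConfig

COND = GrowthCondition("t", 303.15, "aerobic-batch", ngam=0.0)


class TestMaxGrowth:
    def test_uptake_limited_chain(self):
        lp = TemperatureLP.untempered(chain_model(), COND)
        sol = solve_max_growth(lp)
        assert sol.optimal
        assert sol.objective == pytest.approx(10.0)

    def test_enzyme_capacity_limits_chain(self):
        # one enzyme caps A->B at 4 while uptake allows 10: growth = min(10, 4)
        lp = TemperatureLP.untempered(chain_model(enzyme_capacity=4.0), COND)
        sol = solve_max_growth(lp)
        assert sol.objective == pytest.approx(4.0)

    def test_closed_uptake_gives_zero_growth(self):
        model = chain_model()
        model.reaction("UPT").ub = 0.0
        sol = solve_max_growth(TemperatureLP.untempered(model, COND))
        assert sol.optimal and sol.objective == pytest.approx(0.0)

    def test_steady_state_holds(self):
        model = chain_model(enzyme_capacity=4.0)
        lp = TemperatureLP.untempered(model, COND)
        sol = solve_max_growth(lp)
        # recompute S v for every metabolite from the reported net fluxes
        for met in model.metabolites:
            balance = sum(r.stoich.get(met, 0.0) * sol.fluxes[r.id]
                          for r in model.reactions)
            assert abs(balance) < 1e-6


class TestTemperatureInstantiation:
    def make_particle(self, model, tm=330.0, topt=310.0, dcp=-2000.0):
        n = len(model.enzymes)
        return Particle(model.enzyme_ids,
                        np.tile([tm, topt, dcp], n))

    def test_tighter_kcat_never_increases_growth(self):
        model = chain_model(enzyme_capacity=4.0)
        particle = self.make_particle(model)
        cfg = RateLawConfig()
        lp = TemperatureLP(model, particle, COND, cfg)
        tempered = solve_max_growth(lp).objective
        untempered = solve_max_growth(
            TemperatureLP.untempered(model, COND)).objective
        # thermal factors only shrink kcat, so growth can only drop
        assert tempered <= untempered + 1e-9

    def test_halved_kcat_bounds_growth(self):
        model = chain_model(enzyme_capacity=4.0)
        halved = chain_model(enzyme_capacity=2.0)
        g_full = solve_max_growth(TemperatureLP.untempered(model, COND))
        g_half = solve_max_growth(TemperatureLP.untempered(halved, COND))
        assert g_half.objective <= g_full.objective + 1e-9
        assert g_half.objective == pytest.approx(2.0)

    def test_anaerobic_closes_oxygen(self):
        from etcfit.synthetic import build_toy_ecgem, ground_truth_particle
        model = build_toy_ecgem()
        truth = ground_truth_particle(model, np.random.default_rng(0))
        cond = GrowthCondition("an", 303.15, "anaerobic-batch", ngam=1.0)
        sol = solve_max_growth(TemperatureLP(model, truth, cond))
        assert sol.optimal
        assert sol.fluxes["O2_UPT"] == 0.0
        assert sol.fluxes["RESP"] == 0.0

    def test_mismatched_enzyme_list_rejected(self):
        model = chain_model(enzyme_capacity=4.0)
        bad = Particle(("WRONG",), np.array([330.0, 310.0, -2000.0]))
        with pytest.raises(ValueError):
            TemperatureLP(model, bad, COND)

    def test_temperature_outside_validity_rejected(self):
        model = chain_model(enzyme_capacity=4.0)
        particle = self.make_particle(model)
        cold = GrowthCondition("c", 100.0, "aerobic-batch")
        with pytest.raises(ValueError):
            TemperatureLP(model, particle, cold)


def two_pathway_model():
    """Glucose -> ATP via an efficient (2 ATP) or wasteful (1 ATP) pathway."""
    model = ECModel(
        metabolites=["glc", "atp"],
        reactions=[
            Reaction("GLC_UPT", {"glc": 1.0}, 0.0, 10.0),
            Reaction("EFF", {"glc": -1.0, "atp": 2.0}, 0.0, 1000.0),
            Reaction("WASTE", {"glc": -1.0, "atp": 1.0}, 0.0, 1000.0),
            Reaction("BIO", {"atp": -1.0}, 0.0, 1000.0),
        ],
        enzymes=[Enzyme("E_eff", 1.0, 1000.0 / 3600.0, ["EFF"]),
                 Enzyme("E_waste", 1.0, 1000.0 / 3600.0, ["WASTE"])],
        pool=10.0,
        biomass_rxn="BIO",
        exchanges={"glucose": "GLC_UPT"},
    )
    model.validate()
    return model


class TestChemostat:
    def test_dilution_at_max_growth_is_boundary_feasible(self):
        model = chain_model(enzyme_capacity=4.0)
        lp = TemperatureLP.untempered(model, COND)
        mu_max = solve_max_growth(lp).objective
        sol = solve_chemostat(TemperatureLP.untempered(model, COND), mu_max)
        assert sol.optimal
        assert sol.fluxes["UPT"] == pytest.approx(mu_max, rel=1e-6)

    def test_dilution_above_max_growth_infeasible(self):
        model = chain_model(enzyme_capacity=4.0)
        sol = solve_chemostat(TemperatureLP.untempered(model, COND), 5.0)
        assert sol.status == "infeasible"
        assert sol.stage_failed == 1

    def test_glucose_minimum_matches_bruteforce(self):
        # lock growth to 2: brute-force scan over pathway splits gives the
        # minimal uptake 1.0 (all flux through the efficient pathway)
        model = two_pathway_model()
        dilution = 2.0
        sol = solve_chemostat(TemperatureLP.untempered(model, COND), dilution)
        assert sol.optimal

        best = np.inf
        for waste in np.linspace(0.0, dilution, 2001):
            eff = (dilution - waste) / 2.0
            glc = eff + waste
            if glc <= 10.0:
                best = min(best, glc)
        assert sol.fluxes["GLC_UPT"] == pytest.approx(best, abs=1e-6)
        assert sol.fluxes["WASTE"] == pytest.approx(0.0, abs=1e-6)

    def test_stage3_minimizes_protein(self):
        model = two_pathway_model()
        sol = solve_chemostat(TemperatureLP.untempered(model, COND), 2.0)
        # efficient pathway carries 1.0 flux at kcat*3600 = 1000/h
        assert sol.enzyme_usage["E_eff"] == pytest.approx(1.0 / 1000.0,
                                                          rel=1e-6)
        assert sol.enzyme_usage["E_waste"] == pytest.approx(0.0, abs=1e-9)


def parallel_model():
    model = ECModel(
        metabolites=["A", "B"],
        reactions=[
            Reaction("UPT", {"A": 1.0}, 0.0, 6.0),
            Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("P2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIO", {"B": -1.0}, 0.0, 1000.0),
        ],
        enzymes=[],
        pool=1.0,
        biomass_rxn="BIO",
        exchanges={},
    )
    model.validate()
    return model


class TestFVA:
    def test_growth_reaction_range_is_zero(self):
        lp = TemperatureLP.untempered(chain_model(enzyme_capacity=4.0), COND)
        opt = solve_max_growth(lp).objective
        ranges = flux_variability(lp, opt)
        vmin, vmax = ranges["BIO"]
        assert vmax - vmin == 0.0

    def test_unique_pathway_is_locked(self):
        lp = TemperatureLP.untempered(chain_model(enzyme_capacity=4.0), COND)
        opt = solve_max_growth(lp).objective
        ranges = flux_variability(lp, opt)
        for rid in ("UPT", "R1", "R2"):
            vmin, vmax = ranges[rid]
            assert vmin == pytest.approx(opt)
            assert vmax == pytest.approx(opt)

    def test_redundant_pathways_span_full_range(self):
        lp = TemperatureLP.untempered(parallel_model(), COND)
        opt = solve_max_growth(lp).objective
        assert opt == pytest.approx(6.0)
        ranges = flux_variability(lp, opt)
        for rid in ("P1", "P2"):
            vmin, vmax = ranges[rid]
            assert vmin == pytest.approx(0.0)
            assert vmax == pytest.approx(6.0)

    def test_optimum_inside_all_ranges(self):
        lp = TemperatureLP.untempered(parallel_model(), COND)
        sol = solve_max_growth(lp)
        ranges = flux_variability(lp, sol.objective)
        for rid, (vmin, vmax) in ranges.items():
            assert vmin - 1e-9 <= sol.fluxes[rid] <= vmax + 1e-9


class TestModelValidation:
    def test_undeclared_metabolite_named(self):
        with pytest.raises(ModelValidationError, match="ghost"):
            ECModel(metabolites=["A"],
                    reactions=[Reaction("R", {"ghost": 1.0})],
                    enzymes=[], pool=1.0, biomass_rxn="R").validate()

    def test_json_round_trip(self, tmp_path):
        model = chain_model(enzyme_capacity=4.0)
        path = tmp_path / "model.json"
        model.save(path)
        back = ECModel.load(path)
        assert back.to_dict() == model.to_dict()

    def test_schema_version_checked(self, tmp_path):
        import json
        d = chain_model().to_dict()
        d["schema_version"] = 99
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ModelValidationError, match="schema_version"):
            ECModel.load(path)


class TestSBMLImport:
    def test_plain_cobra_model_round_trips_growth(self, tmp_path):
        import cobra

        from etcfit.fba import from_sbml
        cb = cobra.Model("tiny")
        mets = {m: cobra.Metabolite(m, compartment="c") for m in ("A", "B")}
        upt = cobra.Reaction("UPT"); upt.add_metabolites({mets["A"]: 1.0})
        upt.bounds = (0.0, 10.0)
        r1 = cobra.Reaction("R1")
        r1.add_metabolites({mets["A"]: -1.0, mets["B"]: 1.0})
        r1.bounds = (0.0, 1000.0)
        bio = cobra.Reaction("BIO"); bio.add_metabolites({mets["B"]: -1.0})
        bio.bounds = (0.0, 1000.0)
        cb.add_reactions([upt, r1, bio])
        cb.objective = "BIO"
        path = tmp_path / "tiny.xml"
        cobra.io.write_sbml_model(cb, str(path))
        model = from_sbml(path)
        sol = solve_max_growth(TemperatureLP.untempered(model, COND))
        assert sol.objective == pytest.approx(10.0)
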