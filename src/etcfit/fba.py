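"""Enzyme-constrained flux balance analysis (GECKO-style) on top of HiGHS.

The linear program couples metabolic fluxes to explicit enzyme-usage
variables: for every reaction ``j`` catalyzed by enzyme ``e``,

    v_j  <=  kcat_e(T) * 3600 * u_e          (capacity, per enzyme-reaction pair)
    sum_e  MW_e * u_e  <=  P                 (shared protein pool, g/gDW)

with ``v`` in mmol/gDW/h, ``u_e`` in mmol/gDW, MW in g/mmol and kcat in 1/s.
Temperature enters only through the effective kcat values (and the
temperature-dependent non-growth ATP maintenance flux), so a model is
"instantiated" at a (particle, condition) pair and then solved as a plain LP.

Reversible reactions (lb < 0) are split internally into non-negative
forward/backward fluxes; reported fluxes are net.  Named uptake exchanges
(glucose, oxygen) follow the uptake-positive convention of the JSON schema:
closing oxygen for anaerobic growth means clamping its upper bound to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .particles import Particle
from .ratelaw import RateLawConfig, effective_kcat

SCHEMA_VERSION = 1

#: reported fluxes are rounded to this many decimals to suppress solver noise
FLUX_DECIMALS = 10


class ModelValidationError(ValueError):
    """Structural problem in an ECModel definition."""


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0

    @property
    def reversible(self) -> bool:
        return self.lb < 0


@dataclass
class Enzyme:
    id: str
    mw: float          # g/mmol
    kcat_ref: float    # 1/s at the reference state
    reactions: list[str]


@dataclass
class ECModel:
    """Enzyme-constrained metabolic model (stoichiometry + enzyme layer)."""

    metabolites: list[str]
    reactions: list[Reaction]
    enzymes: list[Enzyme]
    pool: float                       # total enzyme mass budget, g/gDW
    biomass_rxn: str
    exchanges: dict[str, str] = field(default_factory=dict)
    ngam_rxn: str | None = None

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        mets = set(self.metabolites)
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoich:
                if m not in mets:
                    raise ModelValidationError(
                        f"reaction {r.id} references undeclared metabolite {m}"
                    )
            if r.lb > r.ub:
                raise ModelValidationError(f"reaction {r.id}: lb > ub")
        rxn_set = set(rxn_ids)
        for e in self.enzymes:
            if not e.reactions:
                raise ModelValidationError(f"enzyme {e.id} catalyzes no reaction")
            for rid in e.reactions:
                if rid not in rxn_set:
                    raise ModelValidationError(
                        f"enzyme {e.id} references unknown reaction {rid}"
                    )
            if e.mw <= 0 or e.kcat_ref <= 0:
                raise ModelValidationError(
                    f"enzyme {e.id}: mw and kcat_ref must be positive"
                )
        if self.pool <= 0:
            raise ModelValidationError("protein pool must be positive")
        if self.biomass_rxn not in rxn_set:
            raise ModelValidationError("biomass reaction not in model")
        if self.ngam_rxn is not None and self.ngam_rxn not in rxn_set:
            raise ModelValidationError("NGAM reaction not in model")
        for role, rid in self.exchanges.items():
            if rid not in rxn_set:
                raise ModelValidationError(
                    f"exchange role {role} references unknown reaction {rid}"
                )

    @property
    def enzyme_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.enzymes)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- JSON schema --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "metabolites": [{"id": m} for m in self.metabolites],
            "reactions": [
                {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub}
                for r in self.reactions
            ],
            "enzymes": [
                {"id": e.id, "mw": e.mw, "kcat_ref": e.kcat_ref,
                 "reactions": e.reactions}
                for e in self.enzymes
            ],
            "pool": self.pool,
            "biomass_rxn": self.biomass_rxn,
            "exchanges": self.exchanges,
            "ngam_rxn": self.ngam_rxn,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ECModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ModelValidationError(
                f"unsupported model schema_version {version!r}; "
                f"this build reads version {SCHEMA_VERSION}"
            )
        model = cls(
            metabolites=[m["id"] for m in d["metabolites"]],
            reactions=[
                Reaction(r["id"], dict(r["stoich"]),
                         float(r.get("lb", 0.0)), float(r.get("ub", 1000.0)))
                for r in d["reactions"]
            ],
            enzymes=[
                Enzyme(e["id"], float(e["mw"]), float(e["kcat_ref"]),
                       list(e["reactions"]))
                for e in d["enzymes"]
            ],
            pool=float(d["pool"]),
            biomass_rxn=d["biomass_rxn"],
            exchanges=dict(d.get("exchanges", {})),
            ngam_rxn=d.get("ngam_rxn"),
        )
        model.validate()
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ECModel":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"malformed model JSON: {exc}") from exc
        return cls.from_dict(d)


@dataclass
class GrowthCondition:
    """One cultivation condition at which the model is evaluated."""

    label: str
    temperature: float                # kelvin
    regime: str                       # aerobic-batch | anaerobic-batch | chemostat
    dilution: float | None = None     # 1/h, chemostat only
    ngam: float = 0.0                 # mmol ATP/gDW/h at this temperature

    def __post_init__(self) -> None:
        if self.regime not in ("aerobic-batch", "anaerobic-batch", "chemostat"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if (self.regime == "chemostat") != (self.dilution is not None):
            raise ValueError("dilution rate must be given iff regime is chemostat")


@dataclass
class FluxSolution:
    status: str                        # optimal | infeasible | unbounded | numeric-failure
    objective: float | None
    fluxes: dict[str, float]
    enzyme_usage: dict[str, float]
    stage_failed: int | None = None    # chemostat stage index on failure

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LINPROG_STATUS = {0: "optimal", 1: "numeric-failure", 2: "infeasible",
                   3: "unbounded", 4: "numeric-failure"}


class TemperatureLP:
    """A model instantiated at one (particle, condition): a mutable LP.

    Variable layout: one forward variable per reaction, one backward variable
    per reversible reaction, then one usage variable per enzyme.
    """

    def __init__(self, model: ECModel, particle: Particle,
                 cond: GrowthCondition, cfg: RateLawConfig | None = None):
        cfg = cfg or RateLawConfig()
        cfg.check_temperature(cond.temperature)
        if tuple(particle.enzyme_ids) != model.enzyme_ids:
            raise ValueError(
                "particle enzyme list does not match the model's enzyme list"
            )
        self.model = model
        self.cond = cond

        kcats = {}
        for eid, params in particle.iter_enzymes():
            enz = next(e for e in model.enzymes if e.id == eid)
            kcats[eid] = effective_kcat(enz.kcat_ref, cond.temperature,
                                        params, cfg)
        self._build(kcats)

    @classmethod
    def untempered(cls, model: ECModel, cond: GrowthCondition) -> "TemperatureLP":
        """Instantiate with the identity rate law (kcat = kcat_ref)."""
        obj = cls.__new__(cls)
        obj.model = model
        obj.cond = cond
        obj._build({e.id: e.kcat_ref for e in model.enzymes})
        return obj

    # -- construction -------------------------------------------------------

    def _build(self, kcats: dict[str, float]) -> None:
        model, cond = self.model, self.cond
        self.fwd: dict[str, int] = {}
        self.bwd: dict[str, int] = {}
        bounds: list[list[float]] = []
        for r in model.reactions:
            self.fwd[r.id] = len(bounds)
            bounds.append([max(r.lb, 0.0), max(r.ub, 0.0)])
            if r.reversible:
                self.bwd[r.id] = len(bounds)
                bounds.append([max(-r.ub, 0.0), -r.lb])
        self.enz: dict[str, int] = {}
        for e in model.enzymes:
            self.enz[e.id] = len(bounds)
            bounds.append([0.0, np.inf])
        self.n_vars = len(bounds)
        self.bounds = np.array(bounds, dtype=float)

        # steady state S v = 0
        met_idx = {m: i for i, m in enumerate(model.metabolites)}
        A_eq = np.zeros((len(model.metabolites), self.n_vars))
        for r in model.reactions:
            for m, coef in r.stoich.items():
                A_eq[met_idx[m], self.fwd[r.id]] += coef
                if r.id in self.bwd:
                    A_eq[met_idx[m], self.bwd[r.id]] -= coef
        self.A_eq = A_eq
        self.b_eq = np.zeros(len(model.metabolites))

        # capacity rows (one per enzyme-reaction pair) + pool row
        rows = []
        rhs = []
        for e in model.enzymes:
            kc_h = kcats[e.id] * 3600.0  # 1/s -> 1/h
            for rid in e.reactions:
                row = np.zeros(self.n_vars)
                row[self.fwd[rid]] = 1.0
                if rid in self.bwd:
                    row[self.bwd[rid]] = 1.0
                row[self.enz[e.id]] = -kc_h
                rows.append(row)
                rhs.append(0.0)
        pool_row = np.zeros(self.n_vars)
        for e in model.enzymes:
            pool_row[self.enz[e.id]] = e.mw
        rows.append(pool_row)
        rhs.append(model.pool)
        self.A_ub = np.array(rows)
        self.b_ub = np.array(rhs)

        # condition adjustments
        if model.ngam_rxn is not None:
            self.set_net_bounds(model.ngam_rxn, cond.ngam, cond.ngam)
        if cond.regime == "anaerobic-batch" and "oxygen" in model.exchanges:
            o2 = model.exchanges["oxygen"]
            # uptake-positive convention: forbid any uptake flux
            self.set_net_bounds(o2, 0.0, 0.0)

    # -- mutation helpers ----------------------------------------------------

    def set_net_bounds(self, rid: str, lb: float, ub: float) -> None:
        """Constrain the net flux of a reaction to [lb, ub]."""
        if rid in self.bwd:
            if lb >= 0:
                self.bounds[self.bwd[rid]] = [0.0, 0.0]
                self.bounds[self.fwd[rid]] = [lb, ub]
            elif ub <= 0:
                self.bounds[self.fwd[rid]] = [0.0, 0.0]
                self.bounds[self.bwd[rid]] = [-ub, -lb]
            else:
                self.bounds[self.fwd[rid]] = [0.0, ub]
                self.bounds[self.bwd[rid]] = [0.0, -lb]
        else:
            self.bounds[self.fwd[rid]] = [max(lb, 0.0), ub]

    def add_ub_row(self, coeffs: dict[int, float], rhs: float) -> None:
        row = np.zeros(self.n_vars)
        for i, c in coeffs.items():
            row[i] = c
        self.A_ub = np.vstack([self.A_ub, row])
        self.b_ub = np.append(self.b_ub, rhs)

    def net_objective(self, rid: str, sense: float = 1.0) -> np.ndarray:
        """Objective vector whose value is sense * (net flux of rid)."""
        c = np.zeros(self.n_vars)
        c[self.fwd[rid]] = sense
        if rid in self.bwd:
            c[self.bwd[rid]] = -sense
        return c

    def protein_mass_objective(self) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for e in self.model.enzymes:
            c[self.enz[e.id]] = e.mw
        return c

    def copy(self) -> "TemperatureLP":
        new = TemperatureLP.__new__(TemperatureLP)
        new.model, new.cond = self.model, self.cond
        new.fwd, new.bwd, new.enz = self.fwd, self.bwd, self.enz
        new.n_vars = self.n_vars
        new.bounds = self.bounds.copy()
        new.A_eq, new.b_eq = self.A_eq, self.b_eq
        new.A_ub, new.b_ub = self.A_ub.copy(), self.b_ub.copy()
        return new

    # -- solving -------------------------------------------------------------

    def solve(self, c_minimize: np.ndarray) -> FluxSolution:
        res = linprog(c_minimize, A_ub=self.A_ub, b_ub=self.b_ub,
                      A_eq=self.A_eq, b_eq=self.b_eq,
                      bounds=self.bounds, method="highs")
        status = _LINPROG_STATUS.get(res.status, "numeric-failure")
        if status != "optimal":
            return FluxSolution(status, None, {}, {})
        fluxes = {}
        for r in self.model.reactions:
            v = res.x[self.fwd[r.id]]
            if r.id in self.bwd:
                v -= res.x[self.bwd[r.id]]
            fluxes[r.id] = round(float(v), FLUX_DECIMALS) + 0.0
        usage = {e.id: round(float(res.x[self.enz[e.id]]), FLUX_DECIMALS) + 0.0
                 for e in self.model.enzymes}
        return FluxSolution("optimal", float(res.fun), fluxes, usage)


def solve_max_growth(lp: TemperatureLP) -> FluxSolution:
    """Maximize the biomass flux; the objective value reported is growth."""
    c = lp.net_objective(lp.model.biomass_rxn, sense=-1.0)
    sol = lp.solve(c)
    if sol.optimal:
        sol.objective = sol.fluxes[lp.model.biomass_rxn]
    return sol


#: relative half-width of the growth-locking band in chemostat solves.
#: A band rather than an equality: sharp equality constraints are the known
#: source of solver instability in this three-stage procedure.
CHEMOSTAT_GROWTH_BAND = 1e-9
CHEMOSTAT_GLC_SLACK = 1e-9


def solve_chemostat(lp: TemperatureLP, dilution: float,
                    growth_band: float = CHEMOSTAT_GROWTH_BAND,
                    glc_slack: float = CHEMOSTAT_GLC_SLACK) -> FluxSolution:
    """Three-stage lexicographic chemostat solve.

    1. lock growth to the dilution rate (two-sided relative band),
    2. minimize glucose uptake, then cap it at that minimum (+slack),
    3. minimize total protein mass and report the exchange fluxes.
    """
    if dilution is None or dilution <= 0:
        raise ValueError("chemostat solve requires a positive dilution rate")
    work = lp.copy()
    half = growth_band * max(dilution, 1.0)
    work.set_net_bounds(lp.model.biomass_rxn, dilution - half, dilution + half)

    glc = lp.model.exchanges["glucose"]
    sol1 = work.solve(work.net_objective(glc, sense=1.0))  # min uptake
    if not sol1.optimal:
        return FluxSolution(sol1.status, None, {}, {}, stage_failed=1)
    min_glc = sol1.fluxes[glc]

    coeffs = {work.fwd[glc]: 1.0}
    if glc in work.bwd:
        coeffs[work.bwd[glc]] = -1.0
    work.add_ub_row(coeffs, min_glc + glc_slack * max(abs(min_glc), 1.0))

    sol3 = work.solve(work.protein_mass_objective())
    if not sol3.optimal:
        return FluxSolution(sol3.status, None, {}, {}, stage_failed=3)
    sol3.objective = dilution
    return sol3


def flux_variability(lp: TemperatureLP, growth_at_optimum: float
                     ) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) net flux with growth locked at its optimum.

    Only the lower bound of the growth reaction is locked, matching standard
    FVA practice.  Per-reaction subproblem failures yield NaN entries rather
    than raising.
    """
    work = lp.copy()
    bio = lp.model.biomass_rxn
    ub_bio = work.bounds[work.fwd[bio]][1]
    work.set_net_bounds(bio, growth_at_optimum, ub_bio)
    out: dict[str, tuple[float, float]] = {}
    for r in lp.model.reactions:
        lo = work.solve(work.net_objective(r.id, sense=1.0))
        hi = work.solve(work.net_objective(r.id, sense=-1.0))
        vmin = lo.fluxes[r.id] if lo.optimal else np.nan
        vmax = hi.fluxes[r.id] if hi.optimal else np.nan
        out[r.id] = (vmin, vmax)
    return out


def from_sbml(path) -> ECModel:
    """Import a (possibly GECKO-style) SBML model into the ECModel schema.

    Maps fbc bounds and stoichiometry directly.  GECKO pseudo-entities are
    recognized by convention: ``prot_<id>`` metabolites define enzymes (their
    draw reactions supply molecular weights; kcats come from the coupling
    coefficients) and a ``prot_pool_exchange`` reaction defines the pool.
    Models without the enzyme layer import with an empty enzyme list.
    Failures are explicit ImportError/ModelValidationError, never silent.
    """
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the optional cobra dependency"
                          ) from exc
    cb = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cb.metabolites
                   if not m.id.startswith("prot_")]
    reactions = []
    enzymes: list[Enzyme] = []
    pool = 1.0
    for rxn in cb.reactions:
        prot_mets = [m for m in rxn.metabolites if m.id.startswith("prot_")]
        if rxn.id == "prot_pool_exchange":
            pool = rxn.upper_bound
            continue
        if rxn.id.startswith("draw_prot_"):
            continue
        stoich = {m.id: float(coef) for m, coef in rxn.metabolites.items()
                  if not m.id.startswith("prot_")}
        reactions.append(Reaction(rxn.id, stoich,
                                  float(rxn.lower_bound), float(rxn.upper_bound)))
        for m in prot_mets:
            coef = rxn.metabolites[m]
            eid = m.id[len("prot_"):]
            kcat = -1.0 / (float(coef) * 3600.0) if coef < 0 else 1.0
            existing = next((e for e in enzymes if e.id == eid), None)
            if existing is None:
                enzymes.append(Enzyme(eid, 1.0, kcat, [rxn.id]))
            else:
                existing.reactions.append(rxn.id)
    objective_rxns = [r.id for r in cb.reactions
                      if r.objective_coefficient not in (0, None)]
    if not objective_rxns:
        raise ModelValidationError("SBML model declares no objective reaction")
    model = ECModel(metabolites=metabolites, reactions=reactions,
                    enzymes=enzymes, pool=pool,
                    biomass_rxn=objective_rxns[0])
    model.validate()
    return model
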