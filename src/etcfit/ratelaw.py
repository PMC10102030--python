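"""Temperature dependence of enzyme catalytic rates.

The effective catalytic rate at temperature ``T`` is modelled as the product
of two factors:

``effective_kcat(T) = kcat_ref * catalytic_factor(T) * folded_fraction(T)``

*Folded fraction* — a two-state van't Hoff denaturation equilibrium with a
temperature-independent unfolding enthalpy ΔH_u::

    ΔG_u(T)        = ΔH_u * (1 - T / Tm)
    folded(T)      = 1 / (1 + exp(-ΔG_u(T) / (R * T)))

so ``folded(Tm) = 0.5`` exactly and the fraction decreases monotonically
with temperature.

*Catalytic factor* — a heat-capacity-curvature rate profile in the spirit of
macromolecular rate theory: the activation free energy carries a constant
activation heat-capacity change ΔC‡p, and the activation enthalpy is anchored
so that ``d log k / dT = 0`` at ``T = Topt`` (which forces the activation
enthalpy at Topt to zero).  That yields the closed form::

    catalytic_factor(T) = exp( (ΔC‡p / R) * ( ln(T/Topt) - (T - Topt)/T ) )

normalized to exactly 1 at ``Topt``; with ΔC‡p < 0 the profile is a smooth
peak at Topt whose width narrows as ΔC‡p grows more negative.  ΔC‡p = 0
degenerates to a flat profile with no interior optimum and is rejected.

The rate law is pluggable: any object with the same three methods can be
used by the FBA layer, so alternative published kcat(T) formulations can be
slotted in without touching the inference machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particles import EnzymeThermalParams

#: universal gas constant, J/(mol K)
R_GAS = 8.314


@dataclass(frozen=True)
class RateLawConfig:
    """Constants of the default thermal rate law.

    ``dH_unfold`` is the (shared) van't Hoff unfolding enthalpy in J/mol;
    300 kJ/mol is a typical order of magnitude for a globular protein and
    sets how sharply activity collapses around Tm.  ``t_min``/``t_max``
    bound the temperature range (K) over which the law is considered valid.
    """

    dH_unfold: float = 3.0e5
    variant: str = "vanthoff-heatcapacity"
    t_min: float = 260.0
    t_max: float = 380.0

    def __post_init__(self) -> None:
        if self.dH_unfold <= 0:
            raise ValueError("unfolding enthalpy must be positive")

    def check_temperature(self, T: float) -> None:
        if not (self.t_min <= T <= self.t_max):
            raise ValueError(
                f"temperature {T} K outside rate-law validity "
                f"range [{self.t_min}, {self.t_max}] K"
            )


def folded_fraction(T: float, Tm: float, cfg: RateLawConfig) -> float:
    """Fraction of enzyme in the folded (active) state at temperature T."""
    if T <= 0 or Tm <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    dG = cfg.dH_unfold * (1.0 - T / Tm)
    return float(1.0 / (1.0 + np.exp(-dG / (R_GAS * T))))


def catalytic_factor(T: float, Topt: float, dCp: float,
                     cfg: RateLawConfig) -> float:
    """Denaturation-free catalytic rate relative to the rate at Topt."""
    if T <= 0 or Topt <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if dCp == 0:
        raise ValueError(
            "dCp = 0 gives a flat rate profile with no interior optimum"
        )
    h = np.log(T / Topt) - (T - Topt) / T
    return float(np.exp((dCp / R_GAS) * h))


def effective_kcat(kcat_ref: float, T: float, params: EnzymeThermalParams,
                   cfg: RateLawConfig) -> float:
    """Effective catalytic rate (1/s) at temperature T, including denaturation."""
    if kcat_ref <= 0:
        raise ValueError("reference kcat must be positive")
    return (kcat_ref
            * catalytic_factor(T, params.Topt, params.dCp, cfg)
            * folded_fraction(T, params.Tm, cfg))
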