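"""Body-mass and temperature scaling of plankton vital rates.

Every rate in the food-web models is a *mass-specific* rate (per unit
biomass, d⁻¹), so a whole-organism allometry ``rate ∝ M^q`` enters the
biomass equations as ``M^(q-1)``.  Three temperature dependencies are
modelled:

* **Metabolism** follows the Arrhenius equation with activation energy
  |E| = 0.56 eV, increasing exponentially over the whole working range.
* **Maximum ingestion** is a unimodal (by default Gaussian) function of
  temperature.  With the size–temperature interaction switched on, the
  thermal optimum declines with body mass — 24, 20 and 16 °C for 0.1, 1
  and 10 μg consumers — so warming favours small over large grazers.
* **Algal carrying capacities** decline exponentially with warming.  The
  two resources share the same density at 20 °C; with the interaction on
  the large-celled resource declines more steeply, so the small resource
  dominates the warm end of the gradient.

A third interaction variant makes the allometric exponent of metabolism
increase with temperature, which penalises large consumers when warm
through their maintenance costs rather than their feeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "BOLTZMANN_EV",
    "KELVIN_OFFSET",
    "ThermalAllometryParams",
    "arrhenius_factor",
    "topt_for_mass",
    "max_ingestion_rate",
    "metabolic_rate",
    "resource_carrying_capacity",
    "rmax_crossover_temperature",
]

#: Boltzmann constant in eV per Kelvin.
BOLTZMANN_EV = 8.617e-5
KELVIN_OFFSET = 273.15

_T_MIN, _T_MAX = -20.0, 60.0


@dataclass(frozen=True)
class ThermalAllometryParams:
    """Allometric and thermal coefficients for one model variant.

    Defaults are the package's calibrated parameterization for pelagic
    plankton (see the methods note); they satisfy the printed anchors:
    ingestion optima 24/20/16 °C at 0.1/1/10 μg, metabolic activation
    energy 0.56 eV, allometric exponent 0.7, and equal resource carrying
    capacities at 20 °C.

    Interaction flags select the model variant: with ``topt_interaction``
    off every consumer has its ingestion optimum at ``topt_ref``; with
    ``rmax_interaction`` off the two resources are dynamically identical;
    ``metab_exponent_interaction`` switches on the temperature-dependent
    metabolic allometric exponent (an alternative interaction mechanism,
    off by default).
    """

    mass_exponent: float = 0.7          # whole-organism allometric exponent
    activation_energy: float = 0.56     # eV, magnitude of metabolic activation
    boltzmann_k: float = BOLTZMANN_EV   # eV K^-1
    t_ref: float = 20.0                 # deg C
    topt_ref: float = 20.0              # deg C, ingestion optimum at 1 ug
    topt_slope: float = 4.0             # deg C decline per decade of mass
    thermal_width: float = 12.0         # deg C, breadth of ingestion curve
    imax_coeff: float = 2.979           # d^-1 at 1 ug and T_opt (calibrated)
    metab_coeff: float = 0.05           # d^-1 at 1 ug and t_ref
    metab_exponent_slope: float = 0.01  # per deg C, used only when flag on
    rmax_ref: float = 100.0             # biomass density at 20 deg C
    rmax_decline_s: float = 0.02        # per deg C, small resource
    rmax_decline_l: float = 0.06        # per deg C, large resource (flag on)
    thermal_kernel: str = "gaussian"    # or "asymmetric"
    topt_interaction: bool = True
    rmax_interaction: bool = True
    metab_exponent_interaction: bool = False

    def __post_init__(self) -> None:
        bad = []
        if not self.activation_energy >= 0:
            bad.append("activation_energy must be >= 0")
        for name in ("thermal_width", "rmax_ref", "imax_coeff"):
            if not getattr(self, name) > 0:
                bad.append(f"{name} must be > 0")
        if self.metab_coeff < 0:
            bad.append("metab_coeff must be >= 0")
        if self.rmax_interaction and not self.rmax_decline_l > self.rmax_decline_s:
            bad.append(
                "rmax_decline_l must exceed rmax_decline_s when the "
                "resource interaction is on"
            )
        if self.thermal_kernel not in ("gaussian", "asymmetric"):
            bad.append(f"unknown thermal_kernel {self.thermal_kernel!r}")
        if bad:
            raise ConfigError("invalid thermal/allometric parameters", bad)

    @property
    def effective_topt_slope(self) -> float:
        """Optimum-vs-mass slope actually applied (0 when the flag is off)."""
        return self.topt_slope if self.topt_interaction else 0.0

    def with_flags(self, topt: bool, rmax: bool, metab_exponent: bool
                   ) -> "ThermalAllometryParams":
        """Copy with the three interaction switches set.

        With the resource interaction off, the large resource inherits the
        small resource's decline coefficient so that the two algae are
        dynamically identical.
        """
        return replace(
            self,
            topt_interaction=topt,
            rmax_interaction=rmax,
            metab_exponent_interaction=metab_exponent,
            rmax_decline_l=self.rmax_decline_l if rmax else self.rmax_decline_s,
        )


def _check_temperature(t: float, name: str = "T") -> float:
    t = float(t)
    if not math.isfinite(t):
        raise InputError(f"{name} must be finite, got {t!r}")
    if not (_T_MIN <= t <= _T_MAX):
        raise InputError(f"{name}={t} outside supported range "
                         f"[{_T_MIN}, {_T_MAX}] deg C")
    return t


def _check_mass(m: float) -> float:
    m = float(m)
    if not (math.isfinite(m) and m > 0):
        raise InputError(f"body mass must be positive and finite, got {m!r}")
    return m


def arrhenius_factor(t: float, e: float = 0.56, t_ref: float = 20.0) -> float:
    """Arrhenius temperature multiplier, equal to 1 at ``t_ref``.

    ``exp(E/k · (1/T_ref − 1/T))`` with temperatures in Kelvin; strictly
    increasing in ``t`` for positive activation energy ``e`` (eV).
    """
    t = _check_temperature(t)
    t_ref = _check_temperature(t_ref, "T_ref")
    tk = t + KELVIN_OFFSET
    tk_ref = t_ref + KELVIN_OFFSET
    return math.exp(e / BOLTZMANN_EV * (1.0 / tk_ref - 1.0 / tk))


def topt_for_mass(m: float, params: ThermalAllometryParams) -> float:
    """Ingestion-rate temperature optimum (°C) for a consumer of mass ``m`` μg.

    Declines by ``topt_slope`` °C per tenfold mass increase when the
    optimum–size interaction is on (24/20/16 °C at 0.1/1/10 μg with the
    defaults); a flat ``topt_ref`` otherwise.
    """
    m = _check_mass(m)
    return params.topt_ref - params.effective_topt_slope * math.log10(m)


def _thermal_kernel(delta: float, params: ThermalAllometryParams) -> float:
    """Unimodal performance kernel, 1 at the optimum.

    Default is a Gaussian of scale ``thermal_width``.  The ``asymmetric``
    variant uses the full width on the cold side and half of it on the warm
    side, emulating the steep supra-optimal decline of empirical thermal
    performance curves.
    """
    w = params.thermal_width
    if params.thermal_kernel == "asymmetric" and delta > 0:
        w = 0.5 * w
    return math.exp(-(delta * delta) / (2.0 * w * w))


def max_ingestion_rate(m: float, t: float, params: ThermalAllometryParams) -> float:
    """Mass-specific maximum ingestion rate (d⁻¹) at mass ``m`` and temp ``t``.

    ``imax_coeff · M^(q−1) · u(T − T_opt(M))`` where q is the allometric
    exponent and u the unimodal thermal kernel. Peaks exactly at the
    mass-dependent optimum.
    """
    m = _check_mass(m)
    t = _check_temperature(t)
    kernel = _thermal_kernel(t - topt_for_mass(m, params), params)
    return params.imax_coeff * m ** (params.mass_exponent - 1.0) * kernel


def metabolic_rate(m: float, t: float, params: ThermalAllometryParams) -> float:
    """Mass-specific metabolic rate (d⁻¹), Arrhenius in T, allometric in M.

    With the metabolic-exponent interaction on, the allometric exponent
    itself warms: ``e(T) = q + slope·(T − T_ref)``, so the relative
    maintenance cost of large consumers grows with temperature.
    """
    m = _check_mass(m)
    t = _check_temperature(t)
    slope = params.metab_exponent_slope if params.metab_exponent_interaction else 0.0
    exponent = params.mass_exponent + slope * (t - params.t_ref)
    return (params.metab_coeff * m ** (exponent - 1.0)
            * arrhenius_factor(t, params.activation_energy, params.t_ref))


def resource_carrying_capacity(resource: str, t: float,
                               params: ThermalAllometryParams) -> float:
    """Maximum (consumer-free equilibrium) biomass density of a resource.

    ``rmax_ref · exp(−c_j (T − T_ref))``; both resources share ``rmax_ref``
    at the reference temperature, so the decline coefficients pin their
    crossover to 20 °C by construction.  ``resource`` is ``"RS"`` (small
    algae) or ``"RL"`` (large algae).
    """
    t = _check_temperature(t)
    if resource == "RS":
        c = params.rmax_decline_s
    elif resource == "RL":
        c = params.rmax_decline_l if params.rmax_interaction else params.rmax_decline_s
    else:
        raise InputError(f"unknown resource {resource!r}; expected 'RS' or 'RL'")
    return params.rmax_ref * math.exp(-c * (t - params.t_ref))


def rmax_crossover_temperature(params: ThermalAllometryParams,
                               t_lo: float = 0.0, t_hi: float = 45.0) -> float:
    """Temperature at which the two resource carrying capacities are equal.

    Solved numerically from the two curves rather than read off the
    construction, so a mis-parameterized set is caught.  Requires the
    resource interaction to be on (otherwise the curves coincide
    everywhere and the crossover is undefined).
    """
    if not params.rmax_interaction:
        raise InputError("crossover undefined: resource curves are identical")
    from scipy.optimize import brentq

    def gap(t: float) -> float:
        return (resource_carrying_capacity("RS", t, params)
                - resource_carrying_capacity("RL", t, params))

    # gap < 0 cold (RL dominates), > 0 warm
    if gap(t_lo) > 0 or gap(t_hi) < 0:
        from .errors import NumericalError
        raise NumericalError(
            f"resource curves do not cross within [{t_lo}, {t_hi}] deg C")
    return float(brentq(gap, t_lo, t_hi, xtol=1e-10))


def as_array_arrhenius(t: np.ndarray, e: float, t_ref: float) -> np.ndarray:
    """Vectorised Arrhenius factor (no range checks; internal use)."""
    tk = np.asarray(t, dtype=float) + KELVIN_OFFSET
    return np.exp(e / BOLTZMANN_EV * (1.0 / (t_ref + KELVIN_OFFSET) - 1.0 / tk))
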