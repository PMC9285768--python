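"""Bioenergetic food-web models for competing zooplankton grazers.

Three community modules share two semichemostat algal resources (small RS,
large RL):

* **Community I** — two unstructured consumer species, small CS and large CL.
* **Community II** — one consumer species with juvenile (J) and adult (A)
  biomass compartments linked by food-dependent maturation and reproduction.
* **Community III** — two stage-structured species spanning three size
  classes; the adult of the small species (AS) and the juvenile of the
  large species (JL) share a body mass and compete most directly.

Resources renew toward a temperature-dependent carrying capacity,
``dR/dt = δ(Rmax(T) − R) − grazing``.  Consumers feed with a type-II
(Monod) functional response on the preference-weighted sum of the two
resources, convert intake to biomass with efficiency β, and pay
temperature-dependent metabolic costs and a constant background
mortality μ.  The diet preference p sets niche separation: at p = 1 the
two competitors in Communities I/II use fully distinct resources, at
p = 0.5 their diets are identical.

Stage structure follows the two-compartment biomass approximation of a
size-structured population: juveniles mature at a food-dependent rate γ,
adults spend all positive net production on reproduction (appearing
instantaneously as juvenile biomass) and never grow, and either stage
shrinks through starvation when its net production ν = β·I − m is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .thermal import (
    ThermalAllometryParams,
    max_ingestion_rate,
    metabolic_rate,
    resource_carrying_capacity,
)

__all__ = [
    "ConsumerCompartment",
    "ParameterSet",
    "CommunityConfig",
    "diet_weights",
    "functional_response",
    "net_production",
    "maturation_rate",
    "rhs",
    "state_labels",
    "state_series",
    "CommunityDynamics",
    "dynamics_for",
]

RESOURCES = ("RS", "RL")


@dataclass(frozen=True)
class ConsumerCompartment:
    """One consumer biomass compartment (a species or a life stage)."""

    id: str
    species: str
    role: str                      # "unstructured" | "juvenile" | "adult"
    mass: float                    # ug dry mass
    diet: tuple[float, float]      # weights on (RS, RL), summing to 1

    def __post_init__(self) -> None:
        if self.role not in ("unstructured", "juvenile", "adult"):
            raise ConfigError(f"unknown role {self.role!r}")
        if not self.mass > 0:
            raise ConfigError(f"compartment {self.id}: mass must be > 0")
        if len(self.diet) != 2 or min(self.diet) < -1e-12:
            raise ConfigError(f"compartment {self.id}: diet weights invalid")
        if abs(sum(self.diet) - 1.0) > 1e-9:
            raise ConfigError(
                f"compartment {self.id}: diet weights must sum to 1")


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and switches for one model variant.

    ``provenance`` tags every numeric value as either ``calibrated-default``
    (this package's parameterization, pinned to the printed anchors) or
    ``transcribed-table`` (a user-supplied transcription of the original table).
    """

    thermal: ThermalAllometryParams = field(default_factory=ThermalAllometryParams)
    delta: float = 0.1              # d^-1, semichemostat supply rate
    half_saturation: float = 40.0   # biomass density
    conversion_efficiency: float = 0.6
    mortality: float = 0.01         # d^-1, background, per compartment
    mortality_overrides: tuple[tuple[str, float], ...] = ()
    functional_response_mode: str = "shared"   # or "independent"
    community3_mapping: str = "blend"          # or "swap"
    provenance: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        bad = []
        if self.delta < 0:
            bad.append("delta must be >= 0")
        if not self.half_saturation > 0:
            bad.append("half_saturation must be > 0")
        if not 0 < self.conversion_efficiency <= 1:
            bad.append("conversion_efficiency must be in (0, 1]")
        if self.mortality < 0 or any(v < 0 for _, v in self.mortality_overrides):
            bad.append("mortality must be >= 0")
        if self.functional_response_mode not in ("shared", "independent"):
            bad.append(f"unknown functional_response_mode "
                       f"{self.functional_response_mode!r}")
        if self.community3_mapping not in ("blend", "swap"):
            bad.append(f"unknown community3_mapping {self.community3_mapping!r}")
        if bad:
            raise ConfigError("invalid parameter set", bad)

    def mortality_of(self, compartment_id: str) -> float:
        return dict(self.mortality_overrides).get(compartment_id, self.mortality)

    @property
    def provenance_map(self) -> dict[str, str]:
        return dict(self.provenance)


@dataclass(frozen=True)
class CommunityConfig:
    """A fully specified community: kind, compartments, p, T, parameters."""

    kind: str                                   # "I" | "II" | "III"
    compartments: tuple[ConsumerCompartment, ...]
    p: float
    temperature: float                          # deg C
    params: ParameterSet

    def __post_init__(self) -> None:
        if self.kind not in ("I", "II", "III"):
            raise ConfigError(f"unknown community kind {self.kind!r}")
        lo = 0.0 if self.kind == "III" else 0.5
        if not (lo - 1e-12 <= self.p <= 1.0 + 1e-12):
            raise ConfigError(
                f"diet preference p={self.p} outside [{lo}, 1] for "
                f"Community {self.kind}")
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate compartment ids")
        for species, pair in self.stage_pairs.items():
            j, a = pair
            if not self.compartments[j].mass < self.compartments[a].mass:
                raise ConfigError(
                    f"species {species}: juvenile mass must be below adult mass")

    @property
    def stage_pairs(self) -> dict[str, tuple[int, int]]:
        """(juvenile index, adult index) per structured species."""
        juv: dict[str, int] = {}
        adu: dict[str, int] = {}
        for i, c in enumerate(self.compartments):
            if c.role == "juvenile":
                if c.species in juv:
                    raise ConfigError(f"species {c.species}: two juvenile stages")
                juv[c.species] = i
            elif c.role == "adult":
                if c.species in adu:
                    raise ConfigError(f"species {c.species}: two adult stages")
                adu[c.species] = i
        if set(juv) != set(adu):
            raise ConfigError("each juvenile needs exactly one adult partner")
        return {s: (juv[s], adu[s]) for s in juv}

    @property
    def labels(self) -> tuple[str, ...]:
        return RESOURCES + tuple(c.id for c in self.compartments)

    @property
    def species(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.compartments:
            if c.species not in seen:
                seen.append(c.species)
        return tuple(seen)


def diet_weights(kind: str, compartment: str, p: float,
                 mapping: str = "blend") -> tuple[float, float]:
    """Diet weights on (RS, RL) for one compartment at preference ``p``.

    Communities I and II (p ∈ [0.5, 1]): the small species/stage weights
    (p, 1−p) and the large one (1−p, p), so diets are identical at p = 0.5
    and fully separate at p = 1.

    Community III (p ∈ [0, 1]): the extreme size classes are specialists
    (JS on RS, AL on RL).  Under the default ``blend`` mapping the two
    middle, equal-mass classes use AS → ((1+p)/2, (1−p)/2) and
    JL → ((1−p)/2, (1+p)/2): identical diets at p = 0, disjoint at p = 1.
    The ``swap`` alternative uses AS → (p, 1−p), JL → (1−p, p).
    """
    if kind in ("I", "II"):
        if not 0.5 - 1e-12 <= p <= 1 + 1e-12:
            raise InputError(f"p={p} outside [0.5, 1] for Community {kind}")
        small = {"I": "CS", "II": "J"}[kind]
        large = {"I": "CL", "II": "A"}[kind]
        if compartment == small:
            return (p, 1.0 - p)
        if compartment == large:
            return (1.0 - p, p)
        raise InputError(f"unknown compartment {compartment!r} in "
                         f"Community {kind}")
    if kind == "III":
        if not -1e-12 <= p <= 1 + 1e-12:
            raise InputError(f"p={p} outside [0, 1] for Community III")
        if compartment == "JS":
            return (1.0, 0.0)
        if compartment == "AL":
            return (0.0, 1.0)
        if mapping == "blend":
            if compartment == "AS":
                return ((1 + p) / 2.0, (1 - p) / 2.0)
            if compartment == "JL":
                return ((1 - p) / 2.0, (1 + p) / 2.0)
        else:
            if compartment == "AS":
                return (p, 1.0 - p)
            if compartment == "JL":
                return (1.0 - p, p)
        raise InputError(f"unknown compartment {compartment!r} in Community III")
    raise InputError(f"unknown community kind {kind!r}")


def functional_response(weights: Sequence[float], rs: float, rl: float,
                        imax: float, h: float, mode: str = "shared",
                        ) -> tuple[float, tuple[float, float]]:
    """Type-II multi-resource intake: (total d⁻¹, per-resource split).

    Default ``shared`` mode is an encounter-weighted Monod response: the
    effective food density is E = wS·RS + wL·RL and total intake
    Imax·E/(H+E), split across resources in proportion to their weighted
    densities.  ``independent`` mode saturates each resource separately
    (Imax·wj·Rj/(H+Rj)).
    """
    if h <= 0:
        raise InputError("half-saturation constant must be > 0")
    if rs < 0 or rl < 0:
        raise InputError("resource densities must be non-negative")
    ws, wl = weights
    if mode == "independent":
        i_s = imax * ws * rs / (h + rs)
        i_l = imax * wl * rl / (h + rl)
        return i_s + i_l, (i_s, i_l)
    avail = ws * rs + wl * rl
    denom = h + avail
    i_s = imax * ws * rs / denom
    i_l = imax * wl * rl / denom
    return i_s + i_l, (i_s, i_l)


def net_production(beta: float, ingestion: float, m: float) -> float:
    """Mass-specific net biomass production ν = β·I − m (d⁻¹).

    Negative values are starvation losses; background mortality is *not*
    part of ν and appears separately in the balance equations.
    """
    return beta * ingestion - m


def maturation_rate(nu_j: float, mu_j: float, z: float) -> float:
    """Food-dependent juvenile→adult maturation rate γ (d⁻¹).

    Standard stage-structured biomass-model form
    ``γ = (ν_J − μ_J) / (1 − z^(1 − μ_J/ν_J))`` with juvenile:adult mass
    ratio z, continuously extended through the removable singularity at
    ν_J = μ_J where γ = μ_J / ln(1/z).  Starving juveniles (ν_J ≤ 0) do
    not mature; the rate is clamped at zero.
    """
    if not 0 < z < 1:
        raise InputError(f"mass ratio z={z} must lie in (0, 1)")
    if mu_j < 0:
        raise InputError("juvenile mortality must be >= 0")
    if nu_j <= 0:
        return 0.0
    x = 1.0 - mu_j / nu_j
    log_z = math.log(z)
    arg = x * log_z
    if abs(arg) < 1e-12:
        return max(nu_j / -log_z, 0.0)
    if arg > 50.0:
        # nu_j -> 0+ with mu_j > 0: z**x blows up and gamma -> 0
        return 0.0
    denom = -math.expm1(arg)              # 1 - z**x
    return max((nu_j - mu_j) / denom, 0.0)


class CommunityDynamics:
    """Precompiled right-hand side for one community at fixed (T, p).

    Rates that depend only on the configuration — carrying capacities,
    per-compartment maximum ingestion and metabolism, diet weights — are
    evaluated once, so the per-step cost is a handful of vector
    operations.
    """

    def __init__(self, config: CommunityConfig):
        self.config = config
        p = config.params
        th = p.thermal
        t = config.temperature
        self.n_cons = len(config.compartments)
        self.rmax = np.array([resource_carrying_capacity(r, t, th)
                              for r in RESOURCES])
        self.weights = np.array([c.diet for c in config.compartments])
        self.imax = np.array([max_ingestion_rate(c.mass, t, th)
                              for c in config.compartments])
        self.metab = np.array([metabolic_rate(c.mass, t, th)
                               for c in config.compartments])
        self.mort = np.array([p.mortality_of(c.id)
                              for c in config.compartments])
        self.beta = p.conversion_efficiency
        self.h = p.half_saturation
        self.delta = p.delta
        self.mode = p.functional_response_mode
        self.pairs = [
            (j, a, config.compartments[j].mass / config.compartments[a].mass)
            for j, a in config.stage_pairs.values()
        ]
        self.unstructured = [i for i, c in enumerate(config.compartments)
                             if c.role == "unstructured"]

    def intake(self, rs: float, rl: float) -> tuple[np.ndarray, np.ndarray]:
        """(total intake per compartment, per-resource intake n×2)."""
        w = self.weights
        if self.mode == "independent":
            per = self.imax[:, None] * w * np.array([rs, rl]) / (
                self.h + np.array([rs, rl]))
        else:
            avail = w[:, 0] * rs + w[:, 1] * rl
            per = (self.imax / (self.h + avail))[:, None] * w * np.array([rs, rl])
        return per.sum(axis=1), per

    def __call__(self, y: np.ndarray) -> np.ndarray:
        rs, rl = y[0], y[1]
        c = y[2:]
        total, per = self.intake(rs, rl)
        grazing = per.T @ c                     # (2,) biomass flux to consumers
        dr = self.delta * (self.rmax - np.array([rs, rl])) - grazing
        nu = self.beta * total - self.metab
        dc = np.empty(self.n_cons)
        for i in self.unstructured:
            dc[i] = (nu[i] - self.mort[i]) * c[i]
        for j, a, z in self.pairs:
            gamma = maturation_rate(nu[j], self.mort[j], z)
            repro = max(nu[a], 0.0)
            starv = min(nu[a], 0.0)
            dc[j] = repro * c[a] + nu[j] * c[j] - gamma * c[j] - self.mort[j] * c[j]
            dc[a] = gamma * c[j] + starv * c[a] - self.mort[a] * c[a]
        return np.concatenate((dr, dc))

    def jacobian(self, y: np.ndarray, active: np.ndarray | None = None,
                 rel_step: float = 1e-6) -> np.ndarray:
        """Central finite-difference Jacobian, optionally on a subspace."""
        if active is None:
            active = np.arange(len(y))
        scale = max(float(np.max(np.abs(y))), 1e-6)
        jac = np.empty((len(active), len(active)))
        for col, idx in enumerate(active):
            h = rel_step * max(abs(y[idx]), 1e-3 * scale)
            yp, ym = y.copy(), y.copy()
            yp[idx] += h
            ym[idx] = max(ym[idx] - h, 0.0)
            step = yp[idx] - ym[idx]
            jac[:, col] = (self(yp)[active] - self(ym)[active]) / step
        return jac


@lru_cache(maxsize=256)
def dynamics_for(config: CommunityConfig) -> CommunityDynamics:
    """Cached compiled dynamics for a (hashable, frozen) configuration."""
    return CommunityDynamics(config)


def state_labels(config: CommunityConfig) -> tuple[str, ...]:
    return config.labels


def state_series(config: CommunityConfig, y: np.ndarray) -> pd.Series:
    """Labelled view of a raw state vector."""
    return pd.Series(np.asarray(y, dtype=float), index=list(config.labels))


def _coerce_state(config: CommunityConfig, state) -> np.ndarray:
    labels = config.labels
    if isinstance(state, pd.Series):
        missing = set(labels) - set(state.index)
        if missing:
            raise InputError(f"state is missing compartments {sorted(missing)}")
        y = state.reindex(list(labels)).to_numpy(dtype=float)
    elif isinstance(state, Mapping):
        try:
            y = np.array([state[k] for k in labels], dtype=float)
        except KeyError as err:
            raise InputError(f"state is missing compartment {err}") from None
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (len(labels),):
            raise InputError(
                f"state has shape {y.shape}, expected ({len(labels)},)")
    if not np.all(np.isfinite(y)):
        raise InputError("state contains non-finite entries")
    if np.any(y < 0):
        raise InputError("state contains negative biomass")
    return y


def rhs(state, config: CommunityConfig) -> pd.Series:
    """Time derivative of every compartment at ``state`` (labelled).

    ``state`` may be a labelled Series/mapping or a raw array ordered as
    ``config.labels`` (RS, RL, then consumers).
    """
    y = _coerce_state(config, state)
    dyn = dynamics_for(config)
    return pd.Series(dyn(y), index=list(config.labels))
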