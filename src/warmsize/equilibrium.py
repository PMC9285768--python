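"""Finding and classifying stable states of a configured community.

Strategy: integrate the ODE forward until the trajectory settles, then
polish the near-equilibrium state with a Newton-type root solve on the
persistent compartments.  Forward integration keeps the solver on
attractors (states reachable from actual initial abundances) and away
from unstable equilibria; the polish step brings the residual down to
round-off.  Compartments that fall below the extinction threshold are
truncated to exactly zero and the reduced system is re-solved.
Multistart search from canonical plus randomized initial states detects
coexisting attractors (alternative stable states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .communities import (
    CommunityConfig,
    CommunityDynamics,
    _coerce_state,
    dynamics_for,
    state_series,
)
from .errors import InputError, NumericalError
from .thermal import resource_carrying_capacity

__all__ = [
    "EquilibriumResult",
    "extinction_threshold",
    "find_equilibrium",
    "analytic_equilibrium_1c1r",
    "stability_check",
    "multistart_equilibria",
]

#: Relative extinction threshold: biomass below this fraction of the
#: reference carrying capacity counts as absent.
EXTINCTION_REL = 1e-9
STABILITY_MARGIN = 1e-8
CLUSTER_RTOL = 1e-4


def extinction_threshold(config: CommunityConfig) -> float:
    return EXTINCTION_REL * config.params.thermal.rmax_ref


@dataclass
class EquilibriumResult:
    """A converged (or diagnosed non-equilibrium) state of one community."""

    state: pd.Series
    residual: float
    stable: bool | None               # None = indeterminate / not applicable
    persistent: tuple[str, ...]       # compartment ids above threshold
    converged: bool
    attractor: str = "equilibrium"    # or "nonequilibrium"
    classification: dict = field(default_factory=dict)

    @property
    def consumer_biomass(self) -> pd.Series:
        return self.state.iloc[2:]


def _default_inoculum(config: CommunityConfig) -> np.ndarray:
    th = config.params.thermal
    t = config.temperature
    y = [resource_carrying_capacity("RS", t, th),
         resource_carrying_capacity("RL", t, th)]
    y += [0.01 * th.rmax_ref] * len(config.compartments)
    return np.array(y)


def _polish(dyn: CommunityDynamics, y: np.ndarray, eps: float
            ) -> tuple[np.ndarray, float] | None:
    """Root-solve on positive compartments; zeros stay pinned at zero."""
    active = np.flatnonzero(y > eps)
    zero_mask = np.ones(len(y), dtype=bool)
    zero_mask[active] = False
    # resources are always dynamic
    active = np.union1d(active, [0, 1])

    def reduced(x: np.ndarray) -> np.ndarray:
        full = np.zeros(len(y))
        full[active] = x
        return dyn(full)[active]

    sol = root(reduced, y[active], method="hybr", tol=1e-13)
    if not sol.success:
        return None
    full = np.zeros(len(y))
    full[active] = sol.x
    if np.any(full[active] < -1e-12 * max(1.0, np.max(np.abs(full)))):
        return None
    full = np.clip(full, 0.0, None)
    full[full < eps] = 0.0
    res = float(np.max(np.abs(dyn(full))))
    return full, res


def find_equilibrium(config: CommunityConfig, initial_state=None, *,
                     rel_tol: float = 1e-9, max_time: float = 1e5,
                     check_stability: bool = True) -> EquilibriumResult:
    """Integrate to an attractor, polish, truncate extinct compartments.

    Non-convergence within ``max_time`` model days with a non-contracting
    trajectory is reported as ``attractor="nonequilibrium"`` with the
    time-averaged state, not raised as an error.
    """
    if initial_state is None:
        y = _default_inoculum(config)
    else:
        y = _coerce_state(config, initial_state)
    dyn = dynamics_for(config)
    eps = extinction_threshold(config)
    scale = max(config.params.thermal.rmax_ref, float(np.max(y)), 1.0)

    t_total = 0.0
    window = 200.0
    last_avg = None
    while t_total < max_time:
        sol = solve_ivp(lambda _, s: dyn(np.clip(s, 0.0, None)),
                        (0.0, window), y, method="LSODA",
                        rtol=1e-10, atol=1e-12 * scale)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise NumericalError(
                f"integration failed at t={t_total}: {sol.message}")
        y_new = np.clip(sol.y[:, -1], 0.0, None)
        t_total += window
        drift = np.max(np.abs(y_new - y)) / scale
        y = y_new
        if drift < 1e-5:
            polished = _polish(dyn, y, eps)
            if polished is not None:
                y_eq, res = polished
                if (res < 1e-8 * scale
                        and np.max(np.abs(y_eq - y)) / scale < 1e-2):
                    return _finalize(config, dyn, y_eq, res, eps,
                                     check_stability)
        if drift < rel_tol:
            # settled but unpolishable (e.g. marginal case): accept as-is
            y[y < eps] = 0.0
            res = float(np.max(np.abs(dyn(y))))
            return _finalize(config, dyn, y, res, eps, check_stability)
        avg = float(np.mean(sol.y[2:].sum(axis=0)))
        if window >= 12800.0 and last_avg is not None:
            if abs(avg - last_avg) / scale < 1e-6 and drift > 1e-4:
                # bounded, non-contracting: a cycle or other non-point attractor
                mean_state = np.clip(sol.y.mean(axis=1), 0.0, None)
                return EquilibriumResult(
                    state=state_series(config, mean_state),
                    residual=float(np.max(np.abs(dyn(mean_state)))),
                    stable=None, persistent=_persistent(config, mean_state, eps),
                    converged=False, attractor="nonequilibrium")
        last_avg = avg
        window = min(window * 2.0, 25600.0)

    y[y < eps] = 0.0
    res = float(np.max(np.abs(dyn(y))))
    if res < 1e-8 * scale:
        return _finalize(config, dyn, y, res, eps, check_stability)
    mean_state = y
    return EquilibriumResult(
        state=state_series(config, mean_state), residual=res, stable=None,
        persistent=_persistent(config, mean_state, eps), converged=False,
        attractor="nonequilibrium")


def _persistent(config: CommunityConfig, y: np.ndarray, eps: float
                ) -> tuple[str, ...]:
    labels = config.labels
    return tuple(labels[i] for i in range(2, len(labels)) if y[i] > eps)


def _finalize(config: CommunityConfig, dyn: CommunityDynamics,
              y: np.ndarray, res: float, eps: float,
              check_stability: bool) -> EquilibriumResult:
    stable = None
    if check_stability:
        stable = stability_check(config, y)
    return EquilibriumResult(
        state=state_series(config, y), residual=res, stable=stable,
        persistent=_persistent(config, y, eps), converged=True)


def stability_check(config: CommunityConfig, eq_state) -> bool | None:
    """Linear stability of an equilibrium from the numerical Jacobian.

    Restricted to persistent compartments (extinct compartments are held
    at zero; their transversal eigenvalues are governed by invasion
    growth, which forward integration has already screened).  Returns
    ``None`` when the eigenproblem is ill-conditioned.
    """
    y = _coerce_state(config, eq_state)
    dyn = dynamics_for(config)
    eps = extinction_threshold(config)
    active = np.union1d(np.flatnonzero(y > eps), [0, 1])
    jac = dyn.jacobian(y, active=active)
    if not np.all(np.isfinite(jac)):
        return None
    eig = np.linalg.eigvals(jac)
    if not np.all(eig.real < -STABILITY_MARGIN):
        return False
    return not _invadable(config, dyn, y, eps)


def _invadable(config: CommunityConfig, dyn: CommunityDynamics,
               y: np.ndarray, eps: float) -> bool:
    """Can any extinct compartment grow at the ambient resource levels?

    Transversal stability: an unstructured consumer at zero invades when
    ν − μ > 0; an extinct stage pair invades when the dominant eigenvalue
    of its 2×2 juvenile/adult linearization is positive.
    """
    total, _ = dyn.intake(y[0], y[1])
    nu = dyn.beta * total - dyn.metab
    for i in dyn.unstructured:
        if y[2 + i] <= eps and nu[i] - dyn.mort[i] > STABILITY_MARGIN:
            return True
    from .communities import maturation_rate
    for j, a, z in dyn.pairs:
        if y[2 + j] > eps or y[2 + a] > eps:
            continue
        gamma = maturation_rate(nu[j], dyn.mort[j], z)
        m22 = np.array([
            [nu[j] - gamma - dyn.mort[j], max(nu[a], 0.0)],
            [gamma, min(nu[a], 0.0) - dyn.mort[a]],
        ])
        if np.max(np.linalg.eigvals(m22).real) > STABILITY_MARGIN:
            return True
    return False


def analytic_equilibrium_1c1r(params, p: float, temperature: float, *,
                              mass: float = 1.0, resource: str = "RS",
                              ) -> tuple[float, float, bool]:
    """Closed-form equilibrium of one consumer on one resource.

    With a single resource the model reduces to Rosenzweig–MacArthur
    dynamics with semichemostat resource renewal.  Under the
    encounter-weighted Monod response with diet weight ``w = p`` on the
    resource, the consumer nullcline gives ``w·R* = H(m+μ)/(βImax−(m+μ))``
    and the resource balance ``C* = β·δ·(Rmax − R*)/(m+μ)``.

    Returns ``(R*, C*, viable)``; when the consumer cannot persist
    (precondition ``p·β·Imax > m+μ`` fails, or R* ≥ Rmax) the consumer-free
    equilibrium ``(Rmax, 0, False)`` is returned.
    """
    from .communities import ParameterSet
    if not isinstance(params, ParameterSet):
        raise InputError("params must be a ParameterSet")
    th = params.thermal
    from .thermal import max_ingestion_rate, metabolic_rate
    imax = max_ingestion_rate(mass, temperature, th)
    m = metabolic_rate(mass, temperature, th)
    mu = params.mortality
    beta = params.conversion_efficiency
    h = params.half_saturation
    rmax = resource_carrying_capacity(resource, temperature, th)
    loss = m + mu
    if p * beta * imax <= loss or beta * imax <= loss:
        return rmax, 0.0, False
    r_star = h * loss / (beta * imax - loss) / p
    if r_star >= rmax:
        return rmax, 0.0, False
    c_star = beta * params.delta * (rmax - r_star) / loss
    return r_star, c_star, True


def _canonical_starts(config: CommunityConfig) -> list[np.ndarray]:
    from .scenarios import initial_states
    variants = ["inoculum", "juvenile-heavy", "adult-heavy", "low-both",
                "high-both"]
    if not config.stage_pairs:
        variants = ["inoculum", "low-both", "high-both"]
    return [initial_states(config, v) for v in variants]


def multistart_equilibria(config: CommunityConfig, *, n_random: int = 8,
                          seed: int = 0, check_stability: bool = True,
                          ) -> list[EquilibriumResult]:
    """Distinct stable equilibria reached from a battery of starts.

    Canonical starts (standard inoculum, juvenile- and adult-dominated,
    low and high biomass) plus ``n_random`` seeded log-uniform random
    states.  Results are de-duplicated by relative L∞ distance.
    """
    from .scenarios import initial_states
    eps = extinction_threshold(config)
    starts = _canonical_starts(config)
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        starts.append(initial_states(config, "random", rng=rng))
    found: list[EquilibriumResult] = []
    for y0 in starts:
        res = find_equilibrium(config, y0, check_stability=check_stability)
        if not res.converged or res.stable is False:
            continue
        vec = res.state.to_numpy()
        scale = max(float(np.max(vec)), eps)
        if any(np.max(np.abs(vec - f.state.to_numpy())) / scale < CLUSTER_RTOL
               for f in found):
            continue
        found.append(res)
    return found
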