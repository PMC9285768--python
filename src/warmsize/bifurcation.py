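"""Boundary mapping in the temperature × diet-preference plane.

Persistence, dominance and bistability boundaries are located by
sweeping equilibria over a (T, p) grid and refining each indicator sign
change by bisection in T.  Equilibria along a sweep are warm-started
from the neighbouring temperature (natural-parameter continuation), with
extinct compartments re-seeded at a small inoculum so that invasion
(transcritical) boundaries are detected rather than inherited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import CommunityConfig
from .equilibrium import (
    EquilibriumResult,
    extinction_threshold,
    find_equilibrium,
    multistart_equilibria,
)
from .errors import InputError

__all__ = [
    "BoundaryCurve",
    "PlaneClassification",
    "classify_state",
    "persistence_boundary",
    "dominance_boundary",
    "bistability_region",
    "map_T_p_plane",
]

_REINOCULUM_REL = 1e-3


@dataclass
class BoundaryCurve:
    """Ordered (T, p) points of one boundary type."""

    boundary_type: str            # "persistence" | "dominance" | "bistability"
    subject: str
    points: list[tuple[float, float]] = field(default_factory=list)
    refinement_tol: float = 0.01  # deg C

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["temperature", "p"])


@dataclass
class PlaneClassification:
    """Full raster of community states over the (T, p) plane."""

    table: pd.DataFrame           # one row per grid cell

    def cell(self, temperature: float, p: float) -> pd.Series:
        d = ((self.table.temperature - temperature).abs()
             + (self.table.p - p).abs())
        return self.table.loc[d.idxmin()]


def _species_mass(config: CommunityConfig, species: str) -> float:
    return max(c.mass for c in config.compartments if c.species == species)


def _species_biomass(eq: EquilibriumResult, config: CommunityConfig
                     ) -> dict[str, float]:
    cons = eq.state.iloc[2:]
    out: dict[str, float] = {}
    for comp in config.compartments:
        out[comp.species] = out.get(comp.species, 0.0) + float(cons[comp.id])
    return out


def classify_state(eq: EquilibriumResult, config: CommunityConfig) -> dict:
    """Persistence and dominance classification of one equilibrium.

    Keys: ``persistent_species``, ``label`` (joined persistent set or
    ``consumers-extinct``), ``species_dominance`` (larger-/smaller-species
    id, ``balanced``, or None when fewer than two species persist) and
    ``stage_dominance`` (per structured species: ``juvenile`` / ``adult``
    / ``balanced``).
    """
    eps = extinction_threshold(config)
    totals = _species_biomass(eq, config)
    persistent = tuple(s for s in config.species if totals[s] > eps)
    label = "+".join(persistent) if persistent else "consumers-extinct"

    species_dom = None
    if len(persistent) >= 2:
        ranked = sorted(persistent, key=lambda s: _species_mass(config, s))
        small, large = ranked[0], ranked[-1]
        gap = totals[large] - totals[small]
        if abs(gap) <= 1e-12 * max(totals[large], totals[small]):
            species_dom = "balanced"
        else:
            species_dom = large if gap > 0 else small

    stage_dom: dict[str, str] = {}
    cons = eq.state.iloc[2:]
    for species, (j, a) in config.stage_pairs.items():
        if species not in persistent:
            continue
        bj = float(cons[config.compartments[j].id])
        ba = float(cons[config.compartments[a].id])
        if abs(ba - bj) <= 1e-12 * max(ba, bj, eps):
            stage_dom[species] = "balanced"
        else:
            stage_dom[species] = "adult" if ba > bj else "juvenile"

    return {"persistent_species": persistent, "label": label,
            "species_dominance": species_dom, "stage_dominance": stage_dom}


def _subject_biomass(eq: EquilibriumResult, config: CommunityConfig,
                     subject: str) -> float:
    cons = eq.state.iloc[2:]
    comp_ids = [c.id for c in config.compartments]
    if subject in comp_ids:
        return float(cons[subject])
    species_ids = [c.id for c in config.compartments if c.species == subject]
    if not species_ids:
        raise InputError(f"subject {subject!r} not in community")
    return float(sum(cons[i] for i in species_ids))


def _reinoculate(config: CommunityConfig, state: np.ndarray) -> np.ndarray:
    """Warm start with extinct compartments re-seeded at a small inoculum."""
    y = np.asarray(state, dtype=float).copy()
    floor = _REINOCULUM_REL * config.params.thermal.rmax_ref
    y[2:] = np.maximum(y[2:], floor)
    y[:2] = np.maximum(y[:2], floor)
    return y


def sweep_equilibria(template, p: float, t_grid: np.ndarray, *,
                     direction: str = "forward", start_state=None,
                     check_stability: bool = False,
                     ) -> list[tuple[float, EquilibriumResult]]:
    """Warm-started equilibria along a temperature grid at fixed p."""
    order = np.asarray(t_grid, dtype=float)
    if direction == "backward":
        order = order[::-1]
    out = []
    prev = start_state
    for t in order:
        config = template(t, p)
        y0 = None if prev is None else _reinoculate(config, prev)
        eq = find_equilibrium(config, y0, check_stability=check_stability)
        prev = eq.state.to_numpy()
        out.append((float(t), eq))
    if direction == "backward":
        out.reverse()
    return out


def _bisect_indicator(template, p: float, t_lo: float, t_hi: float,
                      state_lo: np.ndarray, state_hi: np.ndarray,
                      indicator, tol_t: float) -> float:
    """Refine a sign change of ``indicator(eq, config)`` between t_lo/t_hi."""
    f_lo = indicator(*_solve(template, t_lo, p, state_lo))
    while t_hi - t_lo > tol_t:
        t_mid = 0.5 * (t_lo + t_hi)
        eq, config = _solve(template, t_mid, p, state_lo)
        if (indicator(eq, config) > 0) == (f_lo > 0):
            t_lo, state_lo = t_mid, eq.state.to_numpy()
        else:
            t_hi, state_hi = t_mid, eq.state.to_numpy()
    return 0.5 * (t_lo + t_hi)


def _solve(template, t: float, p: float, warm_state):
    config = template(t, p)
    y0 = None if warm_state is None else _reinoculate(config, warm_state)
    eq = find_equilibrium(config, y0, check_stability=False)
    return eq, config


def _boundary_scan(template, p_grid, t_grid, indicator, tol_t: float,
                   exclude=None) -> list[tuple[float, float]]:
    points = []
    for p in p_grid:
        sweep = sweep_equilibria(template, p, t_grid)
        vals = []
        for t, eq in sweep:
            config = template(t, p)
            if exclude is not None and exclude(eq, config):
                vals.append(None)
            else:
                vals.append(indicator(eq, config))
        for i in range(len(sweep) - 1):
            a, b = vals[i], vals[i + 1]
            if a is None or b is None:
                continue
            if (a > 0) != (b > 0):
                t_star = _bisect_indicator(
                    template, p, sweep[i][0], sweep[i + 1][0],
                    sweep[i][1].state.to_numpy(),
                    sweep[i + 1][1].state.to_numpy(), indicator, tol_t)
                points.append((t_star, float(p)))
    return points


def persistence_boundary(template, subject: str,
                         t_range=(0.0, 45.0), p_range=None,
                         n_grid=(46, 6), tol_t: float = 0.01) -> BoundaryCurve:
    """Persistence (extinction) boundary of ``subject`` in the (T, p) plane.

    ``subject`` is a compartment id or species label.  For each p the
    indicator ``equilibrium biomass − extinction threshold`` is swept
    along T and every sign change is refined by bisection, so both lower
    and upper thermal limits are found where present.
    """
    p_lo = 0.0 if template.kind == "III" else 0.5
    p_grid = np.linspace(*(p_range or (p_lo, 1.0)), n_grid[1])
    t_grid = np.linspace(*t_range, n_grid[0])
    probe = template(20.0, p_grid[-1])
    eps = extinction_threshold(probe)
    _subject_biomass_check(probe, subject)

    def indicator(eq, config):
        return _subject_biomass(eq, config, subject) - eps

    points = _boundary_scan(template, p_grid, t_grid, indicator, tol_t)
    points.sort(key=lambda tp: (tp[1], tp[0]))
    return BoundaryCurve("persistence", subject, points, tol_t)


def _subject_biomass_check(config: CommunityConfig, subject: str) -> None:
    ids = {c.id for c in config.compartments} | set(config.species)
    if subject not in ids:
        raise InputError(f"subject {subject!r} not in community "
                         f"(have {sorted(ids)})")


def dominance_boundary(template, level: str = "species",
                       t_range=(0.0, 45.0), p_range=None,
                       n_grid=(46, 6), tol_t: float = 0.01,
                       species: str | None = None) -> BoundaryCurve:
    """Boundary where biomass dominance flips between size classes.

    ``level="species"`` compares the summed biomass of the larger vs the
    smaller species; ``level="stage"`` compares adult vs juvenile biomass
    within one structured species (``species`` selects it when the
    community has more than one).  Grid points where either unit is
    extinct are excluded from bracketing.
    """
    probe = template(20.0, 0.9)
    eps = extinction_threshold(probe)
    if level == "stage":
        pairs = probe.stage_pairs
        if not pairs:
            raise InputError("stage-level dominance undefined for an "
                             "unstructured community")
        sp = species or next(iter(pairs))
        j_id = probe.compartments[pairs[sp][0]].id
        a_id = probe.compartments[pairs[sp][1]].id

        def indicator(eq, config):
            cons = eq.state
            return float(cons[a_id] - cons[j_id])

        def exclude(eq, config):
            cons = eq.state
            return cons[a_id] + cons[j_id] <= 2 * eps
        subject = f"{sp}:adult-vs-juvenile"
    elif level == "species":
        if len(probe.species) < 2:
            raise InputError("species-level dominance needs two species")
        ranked = sorted(probe.species, key=lambda s: _species_mass(probe, s))
        small, large = ranked[0], ranked[-1]

        def indicator(eq, config):
            totals = _species_biomass(eq, config)
            return totals[large] - totals[small]

        def exclude(eq, config):
            totals = _species_biomass(eq, config)
            return totals[large] <= eps or totals[small] <= eps
        subject = f"{large}-vs-{small}"
    else:
        raise InputError(f"unknown dominance level {level!r}")

    p_lo = 0.0 if template.kind == "III" else 0.5
    p_grid = np.linspace(*(p_range or (p_lo, 1.0)), n_grid[1])
    t_grid = np.linspace(*t_range, n_grid[0])
    points = _boundary_scan(template, p_grid, t_grid, indicator, tol_t,
                            exclude=exclude)
    points.sort(key=lambda tp: (tp[1], tp[0]))
    return BoundaryCurve("dominance", subject, points, tol_t)


def bistability_region(template, t_range=(0.0, 45.0), p_range=None,
                       n_grid=(16, 6), tol_t: float = 0.1, seed: int = 0,
                       n_random: int = 4) -> tuple[BoundaryCurve, pd.DataFrame]:
    """Cells with ≥ 2 distinct stable states, plus the refined T-boundary.

    Returns ``(curve, mask)`` where ``mask`` has one row per grid cell
    with the number of distinct stable states found by multistart.
    """
    p_lo = 0.0 if template.kind == "III" else 0.5
    p_grid = np.linspace(*(p_range or (p_lo, 1.0)), n_grid[1])
    t_grid = np.linspace(*t_range, n_grid[0])
    rows = []
    counts = {}
    for p in p_grid:
        for t in t_grid:
            config = template(float(t), float(p))
            states = multistart_equilibria(config, seed=seed,
                                           n_random=n_random)
            counts[(float(t), float(p))] = len(states)
            rows.append({"temperature": float(t), "p": float(p),
                         "n_states": len(states)})
    mask = pd.DataFrame(rows)

    def count_at(t: float, p: float) -> int:
        config = template(t, p)
        return len(multistart_equilibria(config, seed=seed,
                                         n_random=n_random))

    points = []
    for p in p_grid:
        for i in range(len(t_grid) - 1):
            c0 = counts[(float(t_grid[i]), float(p))] >= 2
            c1 = counts[(float(t_grid[i + 1]), float(p))] >= 2
            if c0 != c1:
                lo, hi = float(t_grid[i]), float(t_grid[i + 1])
                while hi - lo > tol_t:
                    mid = 0.5 * (lo + hi)
                    if (count_at(mid, float(p)) >= 2) == c0:
                        lo = mid
                    else:
                        hi = mid
                points.append((0.5 * (lo + hi), float(p)))
    points.sort(key=lambda tp: (tp[1], tp[0]))
    return BoundaryCurve("bistability", "stable-state-count", points,
                         tol_t), mask


def map_T_p_plane(template, t_range=(0.0, 45.0), p_range=None,
                  n_grid=(16, 6), seed: int = 0,
                  count_states: bool = False) -> PlaneClassification:
    """Raster of persistence/dominance classification over the plane."""
    p_lo = 0.0 if template.kind == "III" else 0.5
    p_grid = np.linspace(*(p_range or (p_lo, 1.0)), n_grid[1])
    t_grid = np.linspace(*t_range, n_grid[0])
    rows = []
    for p in p_grid:
        sweep = sweep_equilibria(template, float(p), t_grid)
        for t, eq in sweep:
            config = template(t, float(p))
            cls = classify_state(eq, config)
            row = {"temperature": t, "p": float(p), "label": cls["label"],
                   "species_dominance": cls["species_dominance"]}
            for sp, dom in cls["stage_dominance"].items():
                row[f"stage_dominance_{sp}"] = dom
            for comp in config.compartments:
                row[f"biomass_{comp.id}"] = float(eq.state[comp.id])
            if count_states:
                row["n_states"] = len(multistart_equilibria(config, seed=seed,
                                                            n_random=4))
            rows.append(row)
    return PlaneClassification(pd.DataFrame(rows))
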