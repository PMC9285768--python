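"""Temperature sweeps of equilibrium biomass and derived size statistics.

A sweep runs warm-started equilibria forward and backward along a
temperature grid at fixed diet preference.  Where the two directions
settle on distinguishable states the community is bistable and both
branches are reported (hysteresis).  Mean individual body mass is the
biomass-weighted harmonic-type estimator ΣB / Σ(B/M): the model tracks
biomass only, so B/M is the implied number of individuals in a
compartment of body mass M.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bifurcation import classify_state, sweep_equilibria
from .communities import CommunityConfig
from .equilibrium import CLUSTER_RTOL, extinction_threshold
from .errors import InputError

__all__ = [
    "mean_body_mass",
    "biomass_vs_temperature",
    "dominance_shift_temperature",
]


def mean_body_mass(state, config: CommunityConfig) -> float:
    """Abundance-weighted mean individual mass (μg) of the consumers.

    ``Σ B_i / Σ (B_i / M_i)`` over consumer compartments.  Raises
    :class:`InputError` when all consumers are extinct (undefined).
    """
    if isinstance(state, pd.Series):
        cons = np.array([state[c.id] for c in config.compartments])
    else:
        cons = np.asarray(state, dtype=float)[2:]
    masses = np.array([c.mass for c in config.compartments])
    total = cons.sum()
    if total <= 0:
        raise InputError("mean body mass undefined: no consumer biomass")
    return float(total / np.sum(cons / masses))


def _sweep_rows(template, p, sweep, branch: str) -> list[dict]:
    rows = []
    for t, eq in sweep:
        config = template(t, p)
        cls = classify_state(eq, config)
        row = {"temperature": t, "p": p, "branch": branch,
               "label": cls["label"],
               "species_dominance": cls["species_dominance"],
               "residual": eq.residual, "converged": eq.converged}
        for sp, dom in cls["stage_dominance"].items():
            row[f"stage_dominance_{sp}"] = dom
        for name in eq.state.index:
            row[f"biomass_{name}"] = float(eq.state[name])
        total_cons = float(eq.state.iloc[2:].sum())
        row["mean_mass"] = (mean_body_mass(eq.state, config)
                            if total_cons > 0 else np.nan)
        rows.append(row)
    return rows


def biomass_vs_temperature(template, p: float, t_grid=None,
                           seed: int = 0) -> pd.DataFrame:
    """Equilibrium biomass along a temperature gradient at fixed p.

    Runs a forward (cold→warm) and a backward sweep; where they disagree
    beyond the clustering tolerance, both rows are kept under distinct
    ``branch`` ids, exposing alternative stable states.  Where they
    agree, only the forward branch is reported.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 45.01, 0.25)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise InputError("t_grid must be strictly increasing")
    fwd = sweep_equilibria(template, p, t_grid, direction="forward")
    bwd = sweep_equilibria(template, p, t_grid, direction="backward")
    rows = _sweep_rows(template, p, fwd, "forward")
    scale = max(template(20.0, p).params.thermal.rmax_ref, 1.0)
    back_rows = []
    for (t, eq_f), (t2, eq_b) in zip(fwd, bwd):
        gap = np.max(np.abs(eq_f.state.to_numpy() - eq_b.state.to_numpy()))
        if gap / scale > CLUSTER_RTOL:
            back_rows += _sweep_rows(template, p, [(t, eq_b)], "backward")
    return pd.DataFrame(rows + back_rows)


def dominance_shift_temperature(template, p: float, level: str = "species",
                                direction: str | None = None,
                                t_range=(0.0, 45.0), step: float = 0.25,
                                tol_t: float = 0.01, seed: int = 0,
                                species: str | None = None) -> float | None:
    """Temperature of the warming-driven dominance flip at fixed p.

    ``direction`` selects the flip of interest as temperature increases:
    at species level the default ``"to_smaller"`` (larger-species
    dominance giving way to the smaller species), at stage level
    ``"to_adult"`` (juvenile dominance giving way to adults);
    ``"to_larger"`` / ``"to_juvenile"`` select the reverse and ``"any"``
    accepts either.  Returns the bisection-refined flip temperature, or
    ``None`` when no such flip occurs within the jointly persistent
    range.  With several qualifying flips the warmest is returned.
    """
    from .bifurcation import (_bisect_indicator, _species_biomass,
                              _species_mass)
    probe = template(20.0, p)
    eps = extinction_threshold(probe)
    if level == "species":
        direction = direction or "to_smaller"
        if direction not in ("to_smaller", "to_larger", "any"):
            raise InputError(f"unknown direction {direction!r}")
        ranked = sorted(probe.species,
                        key=lambda s: _species_mass(probe, s))
        small, large = ranked[0], ranked[-1]
        if small == large:
            raise InputError("species-level shift needs two species")
        want_falling = direction == "to_smaller"

        def indicator(eq, config):
            totals = _species_biomass(eq, config)
            return totals[large] - totals[small]

        def alive(eq, config):
            totals = _species_biomass(eq, config)
            return totals[large] > eps and totals[small] > eps
    elif level == "stage":
        direction = direction or "to_adult"
        if direction not in ("to_adult", "to_juvenile", "any"):
            raise InputError(f"unknown direction {direction!r}")
        pairs = probe.stage_pairs
        if not pairs:
            raise InputError("stage-level shift undefined for an "
                             "unstructured community")
        sp = species or next(iter(pairs))
        j_id = probe.compartments[pairs[sp][0]].id
        a_id = probe.compartments[pairs[sp][1]].id
        # indicator J - A so that "to_adult" is a falling sign change too
        want_falling = direction == "to_adult"

        def indicator(eq, config):
            return float(eq.state[j_id] - eq.state[a_id])

        def alive(eq, config):
            return float(eq.state[j_id] + eq.state[a_id]) > 2 * eps
    else:
        raise InputError(f"unknown dominance level {level!r}")

    t_grid = np.arange(t_range[0], t_range[1] + step / 2, step)
    sweep = sweep_equilibria(template, p, t_grid)
    flips = []
    for i in range(len(sweep) - 1):
        (t0, eq0), (t1, eq1) = sweep[i], sweep[i + 1]
        c0, c1 = template(t0, p), template(t1, p)
        if not (alive(eq0, c0) and alive(eq1, c1)):
            continue
        v0, v1 = indicator(eq0, c0), indicator(eq1, c1)
        if (v0 > 0) == (v1 > 0):
            continue
        falling = v0 > 0 > v1
        if direction != "any" and falling != want_falling:
            continue
        flips.append(_bisect_indicator(template, p, t0, t1,
                                       eq0.state.to_numpy(),
                                       eq1.state.to_numpy(),
                                       indicator, tol_t))
    return max(flips) if flips else None
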