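"""Scenario construction: parameter sets, community configs, initial
states, and the literature-review summary fixture.

Everything other modules need as input is generated here, so the whole
pipeline runs without any external download.  Parameter values carry a
provenance tag: ``calibrated-default`` for the package's own
parameterization (pinned to the printed anchors: resource crossover at
20 °C, ingestion optima 24/20/16 °C at 0.1/1/10 μg, activation energy
0.56 eV, allometric exponent 0.7, and the qualitative warming responses
of each community), or ``transcribed-table`` when a user supplies a
transcription of the original parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .communities import (
    CommunityConfig,
    ConsumerCompartment,
    ParameterSet,
    diet_weights,
)
from .errors import ConfigError, InputError
from .thermal import (
    ThermalAllometryParams,
    resource_carrying_capacity,
    rmax_crossover_temperature,
    topt_for_mass,
)

__all__ = [
    "InteractionFlags",
    "NO_INTERACTION",
    "SIZE_TEMP_INTERACTION",
    "default_parameters",
    "community_config",
    "config_template",
    "initial_states",
    "generate_review_fixture",
    "tally_review",
    "save_config",
    "load_config",
    "validate_anchors",
]

#: Default body masses (μg dry mass) per community kind.  Community III
#: spans the three size classes 0.1/1/10 with the small species' adult and
#: the large species' juvenile sharing the middle class; Communities I and
#: II use the upper pair, so their consumers have identical sizes.
DEFAULT_MASSES = {
    "I": {"CS": 1.0, "CL": 10.0},
    "II": {"J": 1.0, "A": 10.0},
    "III": {"JS": 0.1, "AS": 1.0, "JL": 1.0, "AL": 10.0},
}

_SPECIES = {
    "I": {"CS": "CS", "CL": "CL"},
    "II": {"J": "C", "A": "C"},
    "III": {"JS": "S", "AS": "S", "JL": "L", "AL": "L"},
}

_ROLES = {
    "I": {"CS": "unstructured", "CL": "unstructured"},
    "II": {"J": "juvenile", "A": "adult"},
    "III": {"JS": "juvenile", "AS": "adult", "JL": "juvenile", "AL": "adult"},
}


@dataclass(frozen=True)
class InteractionFlags:
    """The three size–temperature interaction switches."""

    topt: bool = True
    rmax: bool = True
    metab_exponent: bool = False


NO_INTERACTION = InteractionFlags(topt=False, rmax=False, metab_exponent=False)
SIZE_TEMP_INTERACTION = InteractionFlags(topt=True, rmax=True,
                                         metab_exponent=False)


def default_parameters(flags: InteractionFlags = SIZE_TEMP_INTERACTION,
                       transcription: str | Path | None = None,
                       ) -> ParameterSet:
    """Parameter set for one model variant.

    With ``transcription`` given, values are read verbatim from a YAML
    file (provenance ``transcribed-table``) and validated against the printed
    anchors; violations raise :class:`ConfigError` listing every failure.
    Otherwise the calibrated defaults are returned.
    """
    if transcription is not None:
        params = _load_parameter_file(Path(transcription), flags)
        violations = validate_anchors(params)
        if violations:
            raise ConfigError(
                f"transcribed parameters at {transcription} violate "
                "calibration anchors", violations)
        return params
    thermal = ThermalAllometryParams().with_flags(
        flags.topt, flags.rmax, flags.metab_exponent)
    prov = tuple(
        (f.name, "calibrated-default")
        for cls in (ThermalAllometryParams, ParameterSet)
        for f in fields(cls)
        if f.name not in ("thermal", "provenance"))
    return ParameterSet(thermal=thermal, provenance=prov)


def validate_anchors(params: ParameterSet) -> list[str]:
    """Check a parameter set against the printed calibration anchors.

    Returns a list of violation messages (empty when valid).  Only the
    anchors that are meaningful for the set's interaction flags are
    checked.
    """
    th = params.thermal
    out = []
    if abs(th.mass_exponent - 0.7) > 1e-9:
        out.append(f"allometric exponent {th.mass_exponent} != 0.7")
    if abs(th.activation_energy - 0.56) > 1e-9:
        out.append(f"activation energy {th.activation_energy} eV != 0.56 eV")
    if th.topt_interaction:
        for mass, want in ((0.1, 24.0), (1.0, 20.0), (10.0, 16.0)):
            got = topt_for_mass(mass, th)
            if abs(got - want) > 1e-6:
                out.append(f"ingestion optimum at {mass} ug is {got}, "
                           f"expected {want} deg C")
    else:
        if abs(topt_for_mass(5.0, th) - th.topt_ref) > 1e-9:
            out.append("optimum must be mass-independent with the flag off")
    if th.rmax_interaction:
        try:
            t_cross = rmax_crossover_temperature(th)
        except Exception as err:  # no crossover at all
            out.append(f"resource crossover not found: {err}")
        else:
            if abs(t_cross - 20.0) > 0.1:
                out.append(f"resource crossover at {t_cross:.2f} deg C, "
                           "expected 20 +- 0.1")
    else:
        for t in (5.0, 35.0):
            if abs(resource_carrying_capacity("RS", t, th)
                   - resource_carrying_capacity("RL", t, th)) > 1e-9:
                out.append("resource curves must coincide with the flag off")
    return out


def community_config(kind: str, p: float, temperature: float,
                     flags: InteractionFlags = SIZE_TEMP_INTERACTION,
                     params: ParameterSet | None = None,
                     overrides: dict | None = None) -> CommunityConfig:
    """Build a fully populated community configuration.

    ``overrides`` may replace masses (``{"mass:CS": 2.0}``), any
    :class:`ParameterSet` field (``{"mortality": 0.05}``), or any thermal
    field (``{"thermal_width": 10.0}``); unknown keys are an error.
    """
    if kind not in DEFAULT_MASSES:
        raise InputError(f"unknown community kind {kind!r}")
    if params is None:
        params = default_parameters(flags)
    masses = dict(DEFAULT_MASSES[kind])
    overrides = dict(overrides or {})
    param_fields = {f.name for f in fields(ParameterSet)} - {"thermal",
                                                             "provenance"}
    thermal_fields = {f.name for f in fields(ThermalAllometryParams)}
    for key, value in overrides.items():
        if key.startswith("mass:"):
            comp = key.split(":", 1)[1]
            if comp not in masses:
                raise ConfigError(f"unknown compartment in override {key!r}")
            masses[comp] = float(value)
        elif key in param_fields:
            params = replace(params, **{key: value})
        elif key in thermal_fields:
            params = replace(params, thermal=replace(params.thermal,
                                                     **{key: value}))
        else:
            raise ConfigError(f"unknown override key {key!r}")
    compartments = tuple(
        ConsumerCompartment(
            id=cid, species=_SPECIES[kind][cid], role=_ROLES[kind][cid],
            mass=masses[cid],
            diet=diet_weights(kind, cid, p, params.community3_mapping))
        for cid in DEFAULT_MASSES[kind])
    return CommunityConfig(kind=kind, compartments=compartments, p=p,
                           temperature=temperature, params=params)


def config_template(kind: str, flags: InteractionFlags = SIZE_TEMP_INTERACTION,
                    overrides: dict | None = None):
    """A callable ``template(T, p) -> CommunityConfig`` for plane sweeps."""
    params = default_parameters(flags)

    def template(temperature: float, p: float) -> CommunityConfig:
        return community_config(kind, p, temperature, flags=flags,
                                params=params, overrides=overrides)

    template.kind = kind
    template.flags = flags
    return template


def initial_states(config: CommunityConfig, variant: str,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Canonical or seeded-random initial state vectors.

    Variants: ``inoculum`` (resources at carrying capacity, 1% of
    ``rmax_ref`` in every consumer compartment), ``juvenile-heavy`` /
    ``adult-heavy`` (stage biomass split 100:1 at a fixed total),
    ``low-both``, ``high-both``, ``resource-only``, and ``random``
    (log-uniform biomasses between the extinction threshold and ten times
    the reference carrying capacity).
    """
    th = config.params.thermal
    t = config.temperature
    rmax = np.array([resource_carrying_capacity(r, t, th)
                     for r in ("RS", "RL")])
    n = len(config.compartments)
    scale = th.rmax_ref

    if variant == "random":
        if rng is None:
            rng = np.random.default_rng(seed)
        from .equilibrium import extinction_threshold
        lo, hi = np.log(extinction_threshold(config)), np.log(10 * scale)
        cons = np.exp(rng.uniform(lo, hi, size=n))
        return np.concatenate((rmax, cons))

    cons = np.full(n, 0.01 * scale)
    if variant == "inoculum":
        pass
    elif variant == "resource-only":
        cons[:] = 0.0
    elif variant == "low-both":
        cons[:] = 1e-4 * scale
    elif variant == "high-both":
        cons[:] = scale
    elif variant in ("juvenile-heavy", "adult-heavy"):
        total = 0.2 * scale
        heavy, light = total * 100 / 101, total / 101
        for i, comp in enumerate(config.compartments):
            if comp.role == "unstructured":
                continue
            is_juv = comp.role == "juvenile"
            want_heavy = is_juv == (variant == "juvenile-heavy")
            cons[i] = heavy if want_heavy else light
    else:
        raise InputError(f"unknown initial-state variant {variant!r}")
    return np.concatenate((rmax, cons))


# --- literature-review fixture ------------------------------------------

#: Printed marginal counts of the review: level x outcome.  164
#: observations from 136 articles (the article count is metadata only;
#: observations are the analysis unit).
REVIEW_MARGINALS = {
    ("interspecific", "smaller"): 91,
    ("interspecific", "larger"): 14,
    ("interspecific", "none"): 18,
    ("intraspecific", "smaller"): 20,
    ("intraspecific", "larger"): 17,
    ("intraspecific", "none"): 4,
}
REVIEW_TOTAL = 164
REVIEW_ARTICLES = 136

#: Synthetic observational fraction per (level, outcome) cell.  The
#: per-design counts are not printed; these fractions encode the stated
#: qualitative pattern that the excess of smaller-shift observations is
#: strongest among observational studies, with an even split elsewhere.
_OBS_FRACTION = {
    ("interspecific", "smaller"): 0.70,
    ("interspecific", "larger"): 0.35,
    ("interspecific", "none"): 0.50,
    ("intraspecific", "smaller"): 0.50,
    ("intraspecific", "larger"): 0.50,
    ("intraspecific", "none"): 0.50,
}


def generate_review_fixture(seed: int = 0) -> pd.DataFrame:
    """Synthetic observation-level table emulating the review summary.

    One row per observation with columns (observation_id, level, design,
    outcome).  The level × outcome marginals equal the printed counts
    exactly; the experimental/observational split within each cell is a
    synthetic, seeded assignment consistent with the review's qualitative
    description (it is not data from the underlying articles).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (level, outcome), count in REVIEW_MARGINALS.items():
        n_obs = int(round(_OBS_FRACTION[(level, outcome)] * count))
        designs = (["observational"] * n_obs
                   + ["experimental"] * (count - n_obs))
        rng.shuffle(designs)
        rows += [(level, d, outcome) for d in designs]
    rng.shuffle(rows)
    table = pd.DataFrame(rows, columns=["level", "design", "outcome"])
    table.insert(0, "observation_id",
                 [f"obs{i + 1:03d}" for i in range(len(table))])
    table.attrs["n_articles"] = REVIEW_ARTICLES
    table.attrs["synthetic_design_split"] = True
    return table


def tally_review(table: pd.DataFrame) -> pd.DataFrame:
    """Counts by level × design × outcome, with marginal totals attached.

    Returns a tidy frame with columns (level, design, outcome, count);
    level totals and the grand total are exposed via ``attrs["totals"]``
    and cross-checked to sum consistently.
    """
    required = {"level", "design", "outcome"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"review table is missing columns {sorted(missing)}")
    valid = {"level": {"interspecific", "intraspecific"},
             "design": {"experimental", "observational"},
             "outcome": {"smaller", "larger", "none"}}
    for col, allowed in valid.items():
        bad = table.loc[~table[col].isin(allowed)]
        if len(bad):
            raise InputError(
                f"invalid {col} value {bad[col].iloc[0]!r} in row "
                f"{bad.index[0]}")
    counts = (table.groupby(["level", "design", "outcome"], observed=True)
              .size().rename("count").reset_index())
    level_totals = table.groupby("level").size().to_dict()
    totals = {"grand": int(len(table)), **{
        f"{lvl}": int(n) for lvl, n in level_totals.items()}}
    if sum(level_totals.values()) != len(table):  # paranoia, never false
        raise InputError("level totals do not sum to the grand total")
    counts.attrs["totals"] = totals
    return counts


# --- config serialization ------------------------------------------------

def save_config(config: CommunityConfig, path: str | Path) -> None:
    """Serialize a community configuration to a YAML file."""
    th = config.params.thermal
    doc = {
        "kind": config.kind,
        "p": config.p,
        "temperature": config.temperature,
        "masses": {c.id: c.mass for c in config.compartments},
        "params": {f.name: getattr(config.params, f.name)
                   for f in fields(ParameterSet)
                   if f.name not in ("thermal", "provenance",
                                     "mortality_overrides")},
        "mortality_overrides": dict(config.params.mortality_overrides),
        "thermal": {f.name: getattr(th, f.name)
                    for f in fields(ThermalAllometryParams)},
        "provenance": dict(config.params.provenance),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> CommunityConfig:
    """Load a community configuration from YAML; unknown keys error."""
    doc = yaml.safe_load(Path(path).read_text())
    known_top = {"kind", "p", "temperature", "masses", "params",
                 "mortality_overrides", "thermal", "provenance"}
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigError(f"unknown keys in {path}", sorted(unknown))
    thermal_fields = {f.name for f in fields(ThermalAllometryParams)}
    bad_th = set(doc.get("thermal", {})) - thermal_fields
    if bad_th:
        raise ConfigError(f"unknown thermal keys in {path}", sorted(bad_th))
    param_fields = {f.name for f in fields(ParameterSet)} - {
        "thermal", "provenance", "mortality_overrides"}
    bad_p = set(doc.get("params", {})) - param_fields
    if bad_p:
        raise ConfigError(f"unknown parameter keys in {path}", sorted(bad_p))
    thermal = ThermalAllometryParams(**doc.get("thermal", {}))
    params = ParameterSet(
        thermal=thermal,
        mortality_overrides=tuple(sorted(
            doc.get("mortality_overrides", {}).items())),
        provenance=tuple(sorted(doc.get("provenance", {}).items())),
        **doc.get("params", {}))
    overrides = {f"mass:{k}": v for k, v in doc.get("masses", {}).items()}
    return community_config(doc["kind"], doc["p"], doc["temperature"],
                            params=params, overrides=overrides)


def _load_parameter_file(path: Path, flags: InteractionFlags) -> ParameterSet:
    doc = yaml.safe_load(path.read_text())
    thermal_fields = {f.name for f in fields(ThermalAllometryParams)}
    param_fields = {f.name for f in fields(ParameterSet)} - {
        "thermal", "provenance", "mortality_overrides"}
    unknown = set(doc) - thermal_fields - param_fields
    if unknown:
        raise ConfigError(f"unknown parameter keys in {path}",
                          sorted(unknown))
    th_kwargs = {k: v for k, v in doc.items() if k in thermal_fields}
    p_kwargs = {k: v for k, v in doc.items() if k in param_fields}
    thermal = ThermalAllometryParams(**th_kwargs).with_flags(
        flags.topt, flags.rmax, flags.metab_exponent)
    prov = tuple((k, "transcribed-table") for k in sorted(doc))
    return ParameterSet(thermal=thermal, provenance=prov, **p_kwargs)
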