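"""Run configuration loading, validation and ready-made fixture sets.

A run config (JSON canonical, YAML accepted) bundles everything a surface
sweep or simulation needs: a hazard-parameter profile (a builtin name or
explicit per-category b/c/d/f values), a genome composition, a hypothesis,
the grid, series truncation control, and — for simulation — genome size and
seed.  Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .pratio import GenomeComposition, HypothesisSpec
from .survival import (
    CATEGORY_LABELS,
    DEFAULT_PROFILE,
    RetentionClassParams,
    SeriesConfig,
    get_profile,
)
from .surface import GridSpec

__all__ = [
    "RunConfig",
    "load_run_config",
    "TABLE_COMPOSITIONS",
    "MO_BETA_VALUES",
    "write_fixture_configs",
]

#: The fifteen (alpha_alt_func, alpha_dos, alpha_non) study compositions:
#: three chance-retention fractions (0.25, 0.50, 0.75), the remainder split
#: between alternative functionalization and dosage balance.
TABLE_COMPOSITIONS: tuple[tuple[float, float, float], ...] = (
    (0.75, 0.0, 0.25),
    (0.60, 0.15, 0.25),
    (0.45, 0.30, 0.25),
    (0.30, 0.45, 0.25),
    (0.15, 0.60, 0.25),
    (0.0, 0.75, 0.25),
    (0.5, 0.0, 0.5),
    (0.4, 0.10, 0.5),
    (0.3, 0.2, 0.5),
    (0.2, 0.3, 0.5),
    (0.1, 0.4, 0.5),
    (0.0, 0.5, 0.5),
    (0.25, 0.0, 0.75),
    (0.1, 0.15, 0.75),
    (0.0, 0.25, 0.75),
)

#: Switching fractions used in the mutational-opportunity sweeps.
MO_BETA_VALUES: tuple[float, ...] = (0.25, 0.50, 0.75)

_TOP_KEYS = {
    "profile", "parameters", "composition", "hypothesis", "grid", "series",
    "simulation", "output",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything one run needs."""

    profile_name: str
    profile: Mapping[str, RetentionClassParams]
    composition: GenomeComposition
    hypothesis: HypothesisSpec
    grid: GridSpec = field(default_factory=GridSpec)
    series: SeriesConfig = field(default_factory=SeriesConfig)
    n_genes: int | None = None
    seed: int | None = None
    output: Mapping[str, str] = field(default_factory=dict)


def _reject_unknown(d: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def _parse_profile(raw: Mapping[str, Any]) -> tuple[str, Mapping[str, RetentionClassParams]]:
    name = raw.get("profile", DEFAULT_PROFILE)
    if "parameters" in raw:
        params = raw["parameters"]
        _reject_unknown(params, set(CATEGORY_LABELS), "parameters")
        profile = {}
        for label in CATEGORY_LABELS:
            p = dict(params[label])
            _reject_unknown(p, {"b", "c", "d", "f", "t_check"}, f"parameters.{label}")
            profile[label] = RetentionClassParams(label=label, **p)
        return "custom", profile
    return name, get_profile(name)


def load_run_config(source: str | os.PathLike | Mapping[str, Any]) -> RunConfig:
    """Load and validate a run config from a JSON/YAML file or a mapping."""
    if isinstance(source, (str, os.PathLike)):
        path = os.fspath(source)
        with open(path) as fh:
            text = fh.read()
        if path.endswith((".yaml", ".yml")):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ValueError("run config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "run config")

    profile_name, profile = _parse_profile(raw)

    comp_raw = raw.get("composition")
    if comp_raw is None:
        raise ValueError("run config requires a 'composition' section")
    _reject_unknown(comp_raw, {"alt_func", "dos", "non"}, "composition")
    comp = GenomeComposition(
        float(comp_raw.get("alt_func", 0.0)),
        float(comp_raw.get("dos", 0.0)),
        float(comp_raw.get("non", 0.0)),
    )

    hyp_raw = raw.get("hypothesis", {"model": "gene_duplicability"})
    _reject_unknown(hyp_raw, {"model", "beta_switch_mo"}, "hypothesis")
    hyp = HypothesisSpec(
        hyp_raw.get("model", "gene_duplicability"),
        float(hyp_raw.get("beta_switch_mo", 0.0)),
    )

    grid_raw = raw.get("grid", {})
    _reject_unknown(grid_raw, {"t_start", "t_step", "n_points"}, "grid")
    grid = GridSpec(**grid_raw)

    series_raw = raw.get("series", {})
    _reject_unknown(series_raw, {"n_max", "rel_tol", "fail_tol"}, "series")
    series = SeriesConfig(**series_raw)

    sim_raw = raw.get("simulation", {})
    _reject_unknown(sim_raw, {"n_genes", "seed", "t1", "t2"}, "simulation")

    output = raw.get("output", {})

    return RunConfig(
        profile_name=profile_name,
        profile=profile,
        composition=comp,
        hypothesis=hyp,
        grid=grid,
        series=series,
        n_genes=sim_raw.get("n_genes"),
        seed=sim_raw.get("seed"),
        output=dict(output),
    )


def write_fixture_configs(directory: str | os.PathLike) -> list[str]:
    """Write the fifteen study compositions (and the three MO beta values)
    as ready-made JSON run configs; returns the written paths."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for alt, dos, non in TABLE_COMPOSITIONS:
        cfg = {
            "profile": DEFAULT_PROFILE,
            "composition": {"alt_func": alt, "dos": dos, "non": non},
            "hypothesis": {"model": "gene_duplicability"},
        }
        name = f"composition_alt{int(round(alt * 100)):02d}_dos" \
               f"{int(round(dos * 100)):02d}_non{int(round(non * 100)):02d}.json"
        path = os.path.join(directory, name)
        with open(path, "w") as fh:
            json.dump(cfg, fh, indent=2)
            fh.write("\n")
        paths.append(path)
    betas = {"beta_switch_mo_values": list(MO_BETA_VALUES)}
    beta_path = os.path.join(directory, "mutational_opportunity_betas.json")
    with open(beta_path, "w") as fh:
        json.dump(betas, fh, indent=2)
        fh.write("\n")
    paths.append(beta_path)
    return paths
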