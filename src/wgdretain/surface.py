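"""Evaluate the probability-ratio statistic over a (t1, t2) grid.

The default grid matches the published sweep: 50 points per axis from 0.01
to 0.50 in steps of 0.01 (the origin is excluded because the statistic is
undefined at t1 = 0).  Surfaces carry their full provenance (composition,
hypothesis, hazard parameters, grid, package version) so that a surface can
be re-evaluated bitwise from its sidecar metadata alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import __version__
from .pratio import GenomeComposition, HypothesisSpec, p_ratio
from .survival import RetentionClassParams, SeriesConfig, get_profile

__all__ = [
    "GridSpec",
    "PRatioSurface",
    "SurfaceSummary",
    "evaluate_surface",
    "summarize_surface",
    "export_surface",
    "read_surface",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform time grid applied identically to the t1 and t2 axes."""

    t_start: float = 0.01
    t_step: float = 0.01
    n_points: int = 50

    def __post_init__(self) -> None:
        if not self.t_start > 0:
            raise ValueError(f"t_start must be > 0, got {self.t_start}")
        if not self.t_step > 0:
            raise ValueError(f"t_step must be > 0, got {self.t_step}")
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")

    def values(self) -> np.ndarray:
        """Grid times, rounded to 10 decimals so exported headers read
        0.3 rather than 0.30000000000000004."""
        return np.round(
            self.t_start + self.t_step * np.arange(self.n_points), 10
        )


@dataclass(frozen=True)
class PRatioSurface:
    """p_ratio values over the (t1, t2) grid, rows indexed by t1."""

    grid: GridSpec
    composition: GenomeComposition
    hypothesis: HypothesisSpec
    values: np.ndarray
    profile_name: str = "konrad2011_adjusted"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_points, self.grid.n_points):
            raise ValueError(
                f"values must be {self.grid.n_points}x{self.grid.n_points}, "
                f"got {v.shape}"
            )
        if not np.all(np.isfinite(v)) or not np.all(v > 0):
            raise ValueError("surface values must be finite and > 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SurfaceSummary:
    """Peak/trough location and the below-one fraction of a surface."""

    max_value: float
    argmax_t1: float
    argmax_t2: float
    min_value: float
    argmin_t1: float
    argmin_t2: float
    fraction_below_one: float


def evaluate_surface(
    comp: GenomeComposition,
    hyp: HypothesisSpec,
    grid: GridSpec | None = None,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
    profile_name: str = "konrad2011_adjusted",
) -> PRatioSurface:
    """p_ratio at every (t1, t2) combination of the grid.

    Category survival curves are evaluated once per axis value and the same
    scalar p_ratio routine is applied pointwise, so a 1x1 grid reproduces
    the scalar call exactly.
    """
    grid = grid if grid is not None else GridSpec()
    times = grid.values()
    values = np.empty((grid.n_points, grid.n_points), dtype=float)
    for i, t1 in enumerate(times):
        for j, t2 in enumerate(times):
            try:
                values[i, j] = p_ratio(comp, float(t1), float(t2), hyp,
                                       profile, series)
            except Exception as exc:
                raise RuntimeError(
                    f"surface evaluation failed at (t1={t1}, t2={t2}): {exc}"
                ) from exc
    return PRatioSurface(grid, comp, hyp, values, profile_name)


#: a grid value counts as "below one" only beyond float rounding noise
_BELOW_ONE_EPS = 1e-12


def summarize_surface(surface: PRatioSurface) -> SurfaceSummary:
    """Max and min with their (t1, t2) locations, and the fraction of grid
    points below 1 (beyond rounding noise).  Ties break toward the smallest
    t1, then t2."""
    times = surface.grid.values()
    v = surface.values
    # np.argmax/argmin scan C-order (row-major = t1-major), which is exactly
    # the smallest-(t1, t2) tie-break
    imax = np.unravel_index(np.argmax(v), v.shape)
    imin = np.unravel_index(np.argmin(v), v.shape)
    return SurfaceSummary(
        max_value=float(v[imax]),
        argmax_t1=float(times[imax[0]]),
        argmax_t2=float(times[imax[1]]),
        min_value=float(v[imin]),
        argmin_t1=float(times[imin[0]]),
        argmin_t2=float(times[imin[1]]),
        fraction_below_one=float(np.mean(v < 1.0 - _BELOW_ONE_EPS)),
    )


def _sidecar_path(destination: str | os.PathLike) -> str:
    base, _ = os.path.splitext(os.fspath(destination))
    return base + ".meta.json"


def export_surface(surface: PRatioSurface, destination: str | os.PathLike) -> str:
    """Write the surface as TSV plus a JSON sidecar; returns the sidecar path.

    The TSV has a header row of t2 values and a leading column of t1 values;
    ratios are written with ``repr`` so re-importing round-trips bitwise.
    """
    destination = os.fspath(destination)
    times = surface.grid.values()
    try:
        with open(destination, "w") as fh:
            fh.write("t1" + "\t" + "\t".join(repr(float(t)) for t in times) + "\n")
            for i, t1 in enumerate(times):
                row = "\t".join(repr(float(x)) for x in surface.values[i])
                fh.write(f"{float(t1)!r}\t{row}\n")
        sidecar = _sidecar_path(destination)
        meta = {
            "package": "wgdretain",
            "version": __version__,
            "grid": {
                "t_start": surface.grid.t_start,
                "t_step": surface.grid.t_step,
                "n_points": surface.grid.n_points,
            },
            "composition": surface.composition.as_dict(),
            "hypothesis": {
                "model": surface.hypothesis.model,
                "beta_switch_mo": surface.hypothesis.beta_switch_mo,
            },
            "profile_name": surface.profile_name,
            "parameters": {
                label: {"b": p.b, "c": p.c, "d": p.d, "f": p.f}
                for label, p in (get_profile(surface.profile_name)).items()
            },
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed to write surface to {destination!r}: {exc}") from exc
    return sidecar


def read_surface(tsv_path: str | os.PathLike) -> PRatioSurface:
    """Re-import an exported surface (TSV + sidecar) bitwise."""
    tsv_path = os.fspath(tsv_path)
    with open(_sidecar_path(tsv_path)) as fh:
        meta = json.load(fh)
    grid = GridSpec(**meta["grid"])
    comp = GenomeComposition(
        meta["composition"]["alt_func"],
        meta["composition"]["dos"],
        meta["composition"]["non"],
    )
    hyp = HypothesisSpec(**meta["hypothesis"])
    with open(tsv_path) as fh:
        header = fh.readline()
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    values = np.array([[float(x) for x in row[1:]] for row in rows])
    return PRatioSurface(grid, comp, hyp, values, meta["profile_name"])
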