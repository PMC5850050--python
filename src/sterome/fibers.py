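"""Sterome fiber morphometrics.

Raw measurements per fiber cell are the lumen area, the single-wall thickness
at its thinnest and thickest points, and the radial distance of the cell from
the petiole cuticle (all in micrometres).  From these we derive:

* D — lumen diameter of the area-equivalent circle, ``2 * sqrt(A / pi)``;
* t — single-wall thickness, the mean of the thin and thick measurements;
* t/D — the reinforcement ratio of the cell (thicker walls or narrower
  lumina mean a stronger cell);
* FWF — fiber wall fraction, the share of total fiber area occupied by wall
  material, a proxy for carbon investment.

The wall area entering FWF is modeled as a concentric annulus of radial
thickness t around the lumen circle (one cell wall, not the shared double
wall):

    wall_area = pi * ((D/2 + t)^2 - (D/2)^2)
    FWF = wall_area / (lumen_area + wall_area)

This model is isolated in :func:`wall_area_annulus` so alternative wall-area
geometries can be swapped in.

Sterome thickness is aggregated in two stages exactly as measured: sector
values (adaxial, abaxial, lateral) average to a leaf mean, and leaf means
average to the species mean with SD taken over leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import allometry

__all__ = [
    "FIBER_COLUMNS",
    "SECTORS",
    "FiberError",
    "FiberCell",
    "SteromeMeasure",
    "ReinforcementProfile",
    "equivalent_diameter",
    "wall_area_annulus",
    "wall_thickness_for_fwf",
    "fiber_metrics",
    "summarize_species",
    "sterome_summary",
    "reinforcement_profile",
]

#: Required columns of a raw fiber measurement table.
FIBER_COLUMNS = (
    "species",
    "leaf",
    "sector",
    "lumen_area_um2",
    "wall_thin_um",
    "wall_thick_um",
    "distance_um",
)

SECTORS = ("adaxial", "abaxial", "lateral")


class FiberError(ValueError):
    """Invalid fiber measurement input."""


@dataclass(frozen=True)
class FiberCell:
    """One fiber cell's raw measurements (micrometres)."""

    lumen_area: float
    wall_thin: float
    wall_thick: float
    distance_to_cuticle: float
    sector: str = "adaxial"
    leaf: str = "L1"
    species: str = "sp"

    def __post_init__(self) -> None:
        if not self.lumen_area > 0:
            raise FiberError(f"lumen area must be positive, got {self.lumen_area}")
        if not 0 < self.wall_thin <= self.wall_thick:
            raise FiberError(
                f"wall thicknesses must satisfy 0 < thin <= thick, got "
                f"({self.wall_thin}, {self.wall_thick})"
            )
        if self.distance_to_cuticle < 0:
            raise FiberError("distance to cuticle cannot be negative")
        if self.sector not in SECTORS:
            raise FiberError(f"sector must be one of {SECTORS}, got {self.sector!r}")


def equivalent_diameter(lumen_area: float | np.ndarray) -> float | np.ndarray:
    """Diameter (um) of the circle with the same area as the lumen."""
    a = np.asarray(lumen_area, dtype=float)
    if np.any(a <= 0):
        raise FiberError("lumen area must be positive")
    d = 2.0 * np.sqrt(a / math.pi)
    return float(d) if np.isscalar(lumen_area) or d.ndim == 0 else d


def wall_area_annulus(d: float | np.ndarray, t: float | np.ndarray) -> float | np.ndarray:
    """Wall area (um^2) as a concentric annulus of thickness ``t`` around a
    lumen of diameter ``d``."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    out = math.pi * ((d / 2.0 + t) ** 2 - (d / 2.0) ** 2)
    return float(out) if out.ndim == 0 else out


def wall_thickness_for_fwf(d: float, fwf: float) -> float:
    """Invert the annulus model: wall thickness giving fraction ``fwf`` at
    lumen diameter ``d``.

    Solves FWF = wall / (lumen + wall) with the annulus wall area, giving
    t = (d/2) * (sqrt(1 / (1 - FWF)) - 1).
    """
    if not 0 < fwf < 1:
        raise FiberError(f"FWF must lie in (0, 1), got {fwf}")
    return 0.5 * d * (math.sqrt(1.0 / (1.0 - fwf)) - 1.0)


def _validate_fiber_frame(df: pd.DataFrame) -> None:
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise FiberError(f"fiber table missing columns: {', '.join(missing)}")
    bad: list[str] = []
    for idx, row in df.iterrows():
        if not row["lumen_area_um2"] > 0:
            bad.append(f"row {idx}: non-positive lumen area")
        elif not 0 < row["wall_thin_um"] <= row["wall_thick_um"]:
            bad.append(f"row {idx}: wall thicknesses violate 0 < thin <= thick")
        elif row["distance_um"] < 0:
            bad.append(f"row {idx}: negative distance to cuticle")
    if bad:
        raise FiberError("invalid fiber rows: " + "; ".join(bad[:10]))


def fiber_metrics(cells: pd.DataFrame | Iterable[FiberCell]) -> pd.DataFrame:
    """Per-cell derived metrics: D, t, t/D, wall area and FWF.

    Accepts either a raw fiber table (columns :data:`FIBER_COLUMNS`) or an
    iterable of :class:`FiberCell`.  Returns the table with columns
    ``D_um, t_um, t_over_D, wall_area_um2, FWF`` appended.
    """
    if not isinstance(cells, pd.DataFrame):
        cells = pd.DataFrame(
            {
                "species": [c.species for c in cells],
                "leaf": [c.leaf for c in cells],
                "sector": [c.sector for c in cells],
                "lumen_area_um2": [c.lumen_area for c in cells],
                "wall_thin_um": [c.wall_thin for c in cells],
                "wall_thick_um": [c.wall_thick for c in cells],
                "distance_um": [c.distance_to_cuticle for c in cells],
            }
        )
    _validate_fiber_frame(cells)
    out = cells.copy()
    d = 2.0 * np.sqrt(out["lumen_area_um2"].to_numpy(float) / math.pi)
    t = 0.5 * (out["wall_thin_um"].to_numpy(float) + out["wall_thick_um"].to_numpy(float))
    wall = wall_area_annulus(d, t)
    out["D_um"] = d
    out["t_um"] = t
    out["t_over_D"] = t / d
    out["wall_area_um2"] = wall
    out["FWF"] = wall / (out["lumen_area_um2"].to_numpy(float) + wall)
    return out


def summarize_species(cells: pd.DataFrame) -> pd.DataFrame:
    """Species-level means and SDs of the per-cell metrics.

    One row per species with mean and SD of D, t, t/D and FWF plus the cell
    count; SDs use the sample (n-1) convention.
    """
    metrics = fiber_metrics(cells) if "FWF" not in cells.columns else cells
    grouped = metrics.groupby("species")
    rows = []
    for species, g in grouped:
        row = {"species": species, "n_cells": len(g)}
        for col in ("D_um", "t_um", "t_over_D", "FWF"):
            row[f"{col}_mean"] = g[col].mean()
            row[f"{col}_sd"] = g[col].std(ddof=1) if len(g) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SteromeMeasure:
    """Two-stage sterome thickness summary for one species (um)."""

    leaf_means: dict[str, float]
    species_mean: float
    species_sd: float
    n_leaves: int


def sterome_summary(measures: pd.DataFrame) -> SteromeMeasure:
    """Two-stage sterome thickness aggregate: sectors -> leaf -> species.

    ``measures`` needs columns ``leaf``, ``sector`` and ``thickness_um``; each
    leaf may carry one to three sector values.  The species mean is the mean
    of leaf means (not the pooled sector mean), with SD over leaf means.
    """
    required = {"leaf", "sector", "thickness_um"}
    if not isinstance(measures, pd.DataFrame) or not required.issubset(measures.columns):
        raise FiberError(f"sterome table needs columns {sorted(required)}")
    if measures.empty:
        raise FiberError("sterome table is empty")
    bad_sectors = set(measures["sector"]) - set(SECTORS)
    if bad_sectors:
        raise FiberError(f"unknown sectors: {sorted(bad_sectors)}")
    if np.any(measures["thickness_um"].to_numpy(float) <= 0):
        raise FiberError("sterome thickness must be positive")
    leaf_means = measures.groupby("leaf")["thickness_um"].mean().to_dict()
    values = np.array(list(leaf_means.values()), dtype=float)
    return SteromeMeasure(
        leaf_means=leaf_means,
        species_mean=float(values.mean()),
        species_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_leaves=len(values),
    )


@dataclass(frozen=True)
class ReinforcementProfile:
    """Radial reinforcement gradient: per-cell (distance, t/D) pairs with a
    log-log SMA trend fit.  ``fit`` is None when the profile is degenerate
    (no relationship between distance and t/D)."""

    table: pd.DataFrame
    fit: "allometry.SMAFit | None"
    degenerate: bool

    @property
    def slope(self) -> float | None:
        return None if self.fit is None else self.fit.slope


def reinforcement_profile(cells: pd.DataFrame) -> ReinforcementProfile:
    """t/D of each fiber versus its distance to the cuticle, with a log-log
    SMA trend.

    Cells at the periphery of real steromes are the most reinforced, so the
    fitted slope is typically negative.  Requires at least three distinct
    distances; a flat profile (r = 0) is flagged degenerate rather than
    raising.
    """
    metrics = fiber_metrics(cells) if "t_over_D" not in cells.columns else cells
    table = metrics[["species", "distance_um", "t_over_D"]].copy()
    distances = table["distance_um"].to_numpy(float)
    if len(np.unique(distances)) < 3:
        raise FiberError("reinforcement profile needs >= 3 distinct distances")
    if np.any(distances <= 0):
        raise FiberError("distances must be positive for the log-log trend fit")
    try:
        fit = allometry.sma_fit(distances, table["t_over_D"].to_numpy(float), log_base=10)
    except allometry.DegenerateFitError:
        return ReinforcementProfile(table=table, fit=None, degenerate=True)
    return ReinforcementProfile(table=table, fit=fit, degenerate=False)
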