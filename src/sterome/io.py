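"""File formats and run configuration.

Cross-sections travel as ``.xsec.json``::

    {"units": "mm",
     "orientation": {"y": "dorsoventral", "x": "lateral"},
     "regions": [{"tissue": "sclerenchyma",
                  "outer": [[x, y], ...],
                  "holes": [[[x, y], ...], ...]}]}

Trait and fiber tables are plain CSV (UTF-8, "." decimal).  Tabular outputs
are written with a JSON sidecar recording units, conventions and the config
hash so any results file is self-describing.

Run configuration is TOML with two sections, ``[moduli]`` (the four tissue
names) and ``[pipeline]``; unknown keys fail fast.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fibers import FIBER_COLUMNS
from .geometry import CrossSection, PolygonOutline, TissueRegion
from .mechanics import STANDARD_GRAVITY, TissueModuli

__all__ = [
    "SchemaError",
    "ConfigError",
    "PipelineConfig",
    "load_config",
    "read_cross_section",
    "write_cross_section",
    "read_trait_table",
    "read_fiber_table",
    "write_table",
]

_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "μm": 1e-3, "cm": 10.0, "m": 1000.0}


class SchemaError(ValueError):
    """An input file violates its schema; message lists every offending field."""


class ConfigError(ValueError):
    """Bad or unknown configuration key."""


def read_cross_section(path: str | Path) -> CrossSection:
    """Read and validate a ``.xsec.json`` file, converting lengths to mm."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    problems: list[str] = []
    units = data.get("units", "mm")
    scale = _UNIT_TO_MM.get(units)
    if scale is None:
        problems.append(f"units: unknown unit {units!r}")
    regions_raw = data.get("regions")
    if not isinstance(regions_raw, list) or not regions_raw:
        problems.append("regions: must be a non-empty list")
        regions_raw = []
    regions = []
    for i, r in enumerate(regions_raw):
        tissue = r.get("tissue")
        outer = r.get("outer")
        if tissue is None:
            problems.append(f"regions[{i}].tissue: missing")
            continue
        if not isinstance(outer, list):
            problems.append(f"regions[{i}].outer: missing or not a vertex list")
            continue
        try:
            outline = PolygonOutline(
                np.asarray(outer, dtype=float) * (scale or 1.0),
                label=f"{path.name} regions[{i}].outer",
            )
            holes = [
                PolygonOutline(
                    np.asarray(h, dtype=float) * (scale or 1.0),
                    label=f"{path.name} regions[{i}].holes[{j}]",
                )
                for j, h in enumerate(r.get("holes", []))
            ]
            regions.append(TissueRegion(tissue, outline, holes))
        except (ValueError, TypeError) as exc:
            problems.append(f"regions[{i}]: {exc}")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return CrossSection(regions, orientation=data.get("orientation"), units="mm")


def write_cross_section(section: CrossSection, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "units": section.units,
        "orientation": section.orientation,
        "regions": [
            {
                "tissue": r.tissue,
                "outer": r.outer.vertices.tolist(),
                "holes": [h.vertices.tolist() for h in r.holes],
            }
            for r in section.regions
        ],
    }
    path.write_text(json.dumps(payload))


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a species trait CSV; species ids must be unique, values positive
    where present."""
    path = Path(path)
    df = pd.read_csv(path)
    problems = []
    if "species" not in df.columns:
        problems.append("missing 'species' column")
    else:
        dupes = df["species"][df["species"].duplicated()].tolist()
        if dupes:
            problems.append(f"duplicate species rows: {sorted(set(dupes))}")
    for col in df.columns:
        if col == "species":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if ((vals <= 0) & df[col].notna()).any():
            problems.append(f"column {col!r}: non-positive values")
        df[col] = vals
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df


def read_fiber_table(path: str | Path) -> pd.DataFrame:
    """Read a raw fiber measurement CSV with the fixed column set."""
    df = pd.read_csv(path)
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: fiber table missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write CSV plus a ``.meta.json`` sidecar with units/conventions."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PIPELINE_KEYS = {
    "g",
    "log_base",
    "buckling_axis",
    "include_petiole_mass",
    "seed",
    "log_level",
}


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    ``buckling_axis`` selects which rigidity enters the Euler criterion:
    'x' (the default) uses the vertical-plane rigidity, i.e. the moment about
    the horizontal axis, appropriate for top-loading by the lamina's weight.
    """

    moduli: TissueModuli = field(default_factory=TissueModuli)
    g: float = STANDARD_GRAVITY
    log_base: float = 10.0
    buckling_axis: str = "x"
    include_petiole_mass: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.buckling_axis not in ("x", "y"):
            raise ConfigError(f"buckling_axis must be 'x' or 'y', got {self.buckling_axis!r}")
        if not self.g > 0:
            raise ConfigError("g must be positive")

    def as_dict(self) -> dict:
        return {
            "moduli": self.moduli.as_dict(),
            "g": self.g,
            "log_base": self.log_base,
            "buckling_axis": self.buckling_axis,
            "include_petiole_mass": self.include_petiole_mass,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML config; unknown sections or keys are rejected."""
    if path is None:
        return PipelineConfig()
    raw = tomllib.loads(Path(path).read_text())
    unknown_sections = set(raw) - {"moduli", "pipeline"}
    if unknown_sections:
        raise ConfigError(f"unknown config sections: {sorted(unknown_sections)}")
    moduli_raw = raw.get("moduli", {})
    tissue_names = set(TissueModuli().as_dict())
    unknown_tissues = set(moduli_raw) - tissue_names
    if unknown_tissues:
        raise ConfigError(f"unknown tissues under [moduli]: {sorted(unknown_tissues)}")
    pipeline_raw = raw.get("pipeline", {})
    unknown_keys = set(pipeline_raw) - _PIPELINE_KEYS
    if unknown_keys:
        raise ConfigError(f"unknown keys under [pipeline]: {sorted(unknown_keys)}")
    return PipelineConfig(moduli=TissueModuli(**moduli_raw), **pipeline_raw)
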