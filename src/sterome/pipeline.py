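"""End-to-end orchestration: sections -> mechanics -> fibers -> allometry -> PIC.

``run_pipeline`` consumes a directory of inputs (any subset of)

* ``sections/*.xsec.json`` — digitized cross-sections, one per specimen,
  named ``<species>_<replicate>.xsec.json``;
* ``traits.csv`` — species trait table;
* ``fibers.csv`` — raw fiber measurements;
* ``tree.nwk`` — rooted phylogeny with branch lengths;

and writes per-specimen mechanical profiles, buckling results, fiber
summaries, the SMA scaling table with PIC columns, and a run manifest.
Stage failures are recorded (with the stage name and offending input) and
remaining stages still run; partial results are persisted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import DEFAULT_PAIRS, scaling_table
from .fibers import reinforcement_profile, summarize_species
from .geometry import tissue_moments
from .io import (
    PipelineConfig,
    read_cross_section,
    read_fiber_table,
    read_trait_table,
    write_table,
)
from .mechanics import buckling_analysis, flexural_rigidity
from .phylo import compute_contrasts, contrast_regression, drop_tips, parse_newick

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger("sterome")


class PipelineError(RuntimeError):
    """One or more pipeline stages failed; message lists stage and input.

    The partial :class:`PipelineResult` (whatever stages completed were
    still written to disk) is available as ``exc.result``.
    """

    def __init__(self, message: str, result: "PipelineResult | None" = None):
        super().__init__(message)
        self.result = result


@dataclass
class PipelineResult:
    mechanics: pd.DataFrame | None = None
    buckling: pd.DataFrame | None = None
    fiber_summary: pd.DataFrame | None = None
    scaling: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


def _mechanics_stage(section_paths: list[Path], config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for p in sorted(section_paths):
        specimen = p.name.removesuffix(".xsec.json")
        species = specimen.split("_")[0]
        section = read_cross_section(p)
        moments = tissue_moments(section)
        profile = flexural_rigidity(moments, config.moduli)
        for axis in ("x", "y"):
            i_map = moments.i_x if axis == "x" else moments.i_y
            row = {
                "specimen": specimen,
                "species": species,
                "axis": axis,
                "area_mm2": moments.total_area,
                "I_mm4": sum(i_map.values()),
                "EI_Nm2": profile.ei[axis],
                "E_composite_MNm2": profile.e_composite[axis],
                "EI_ratio_x_over_y": profile.ei_ratio,
            }
            for tissue, frac in profile.contributions[axis].items():
                row[f"contr_{tissue}"] = frac
            rows.append(row)
    return pd.DataFrame(rows)


def _buckling_stage(traits: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for _, r in traits.iterrows():
        needed = ("EI_Nm2", "leaf_mass_g", "petiole_length_m")
        if any(col not in traits.columns or pd.isna(r[col]) for col in needed):
            log.warning("buckling: species %s missing EI/mass/length, skipped", r["species"])
            continue
        res = buckling_analysis(
            ei=float(r["EI_Nm2"]),
            dry_mass=float(r["leaf_mass_g"]) / 1000.0,
            l_petiole=float(r["petiole_length_m"]),
            g=config.g,
        )
        rows.append(
            {
                "species": r["species"],
                "F_N": res.force,
                "L_max_m": res.l_max,
                "L_petiole_m": res.l_petiole,
                "safety_factor": res.safety_factor,
            }
        )
    return pd.DataFrame(rows)


def _pic_columns(
    scaling: pd.DataFrame,
    traits: pd.DataFrame,
    tree_text: str,
    log_base: float,
) -> pd.DataFrame:
    tree = parse_newick(tree_text)
    on_tree = set(tree.tip_labels)
    scaling = scaling.copy()
    scaling["pic_r2_adj"] = np.nan
    scaling["pic_pvalue"] = np.nan
    indexed = traits.set_index("species")
    for i, row in scaling.iterrows():
        pair = indexed[[row["x"], row["y"]]].dropna()
        usable = [s for s in pair.index if s in on_tree]
        to_drop = sorted(on_tree - set(usable))
        if len(usable) < 3:
            log.warning("PIC: pair (%s, %s) has <3 species on the tree", row["x"], row["y"])
            continue
        if to_drop:
            log.warning(
                "PIC: pruning %s from the tree for pair (%s, %s) (missing data)",
                to_drop,
                row["x"],
                row["y"],
            )
        pruned = drop_tips(tree, to_drop) if to_drop else tree
        lx = {s: np.log(pair.loc[s, row["x"]]) / np.log(log_base) for s in usable}
        ly = {s: np.log(pair.loc[s, row["y"]]) / np.log(log_base) for s in usable}
        cx = compute_contrasts(pruned, lx)
        cy = compute_contrasts(pruned, ly)
        reg = contrast_regression(cx, cy)
        scaling.loc[i, "pic_r2_adj"] = reg.r2_adj
        scaling.loc[i, "pic_pvalue"] = reg.pvalue
    return scaling


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path,
) -> PipelineResult:
    """Run every stage whose inputs exist under ``input_dir``.

    Results are written to ``out_dir`` (created if needed) with metadata
    sidecars; a ``manifest.json`` records the config, seed and package
    version so a run is reproducible byte-for-byte from the same inputs.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    meta_common = {
        "config": config.as_dict(),
        "config_hash": config.digest(),
        "units": {
            "I": "mm^4",
            "EI": "N m^2",
            "E_composite": "MN m^-2",
            "lengths": "m",
            "force": "N",
        },
        "conventions": {
            "axis_x": "moment about the horizontal axis (bending in the vertical plane)",
            "EI_ratio": "EI_x / EI_y",
            "pic": "through-origin regression of y-contrasts on x-contrasts",
        },
    }

    section_paths = sorted(input_dir.glob("sections/*.xsec.json"))
    if section_paths:
        try:
            result.mechanics = _mechanics_stage(section_paths, config)
            write_table(result.mechanics, out_dir / "mechanics.csv", meta_common)
        except Exception as exc:
            result.errors.append(f"mechanics: {exc}")

    traits = None
    traits_path = input_dir / "traits.csv"
    if traits_path.exists():
        try:
            traits = read_trait_table(traits_path)
        except Exception as exc:
            result.errors.append(f"traits: {exc}")

    if traits is not None:
        try:
            result.buckling = _buckling_stage(traits, config)
            write_table(result.buckling, out_dir / "buckling.csv", meta_common)
        except Exception as exc:
            result.errors.append(f"buckling: {exc}")

    fibers_path = input_dir / "fibers.csv"
    fibers = None
    if fibers_path.exists():
        try:
            fibers = read_fiber_table(fibers_path)
            result.fiber_summary = summarize_species(fibers)
            write_table(result.fiber_summary, out_dir / "fiber_summary.csv", meta_common)
        except Exception as exc:
            result.errors.append(f"fibers: {exc}")

    if traits is not None:
        try:
            pairs = [
                (x, y) for x, y in DEFAULT_PAIRS if x in traits.columns and y in traits.columns
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaling = scaling_table(traits, pairs, log_base=config.log_base)
            tree_path = input_dir / "tree.nwk"
            if tree_path.exists() and len(scaling):
                scaling = _pic_columns(scaling, traits, tree_path.read_text(), config.log_base)
            if fibers is not None:
                prof = reinforcement_profile(fibers)
                if prof.fit is not None:
                    scaling = pd.concat(
                        [
                            scaling,
                            pd.DataFrame(
                                [
                                    {
                                        "x": "distance_um",
                                        "y": "t_over_D",
                                        "n": prof.fit.n,
                                        "r": prof.fit.r,
                                        "r2_adj": prof.fit.r2_adj,
                                        "pvalue": prof.fit.pvalue,
                                        "slope": prof.fit.slope,
                                        "elevation": prof.fit.elevation,
                                        "ci_low": prof.fit.ci_low,
                                        "ci_high": prof.fit.ci_high,
                                    }
                                ]
                            ),
                        ],
                        ignore_index=True,
                    )
            result.scaling = scaling
            write_table(scaling, out_dir / "scaling.csv", meta_common)
        except Exception as exc:
            result.errors.append(f"allometry/PIC: {exc}")

    result.manifest = {
        **meta_common,
        "version": __version__,
        "inputs": sorted(str(p.relative_to(input_dir)) for p in input_dir.rglob("*") if p.is_file()),
        "errors": result.errors,
    }
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
    if result.errors:
        raise PipelineError("; ".join(result.errors), result=result)
    return result
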