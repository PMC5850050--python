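"""Synthetic inputs with the statistical structure the pipeline assumes.

Real petiole anatomy is only available as micrographs; for testing and for
exercising the full pipeline we generate idealized but structurally faithful
stand-ins:

* cross-sections — an outer sclerenchyma (sterome) annulus over a parenchyma
  interior with centrally placed circular vascular bundles (xylem core,
  phloem sheath), optionally carved with an adaxial groove that makes the
  outline non-convex;
* species trait tables — stipe diameters log-uniform over the observed
  0.45-12.84 mm range, leaf traits following power laws with multiplicative
  lognormal noise, and all mechanical columns (I, EI, L_max, safety factor)
  filled consistently from the circular idealization and default moduli;
* fiber populations — cells spread through the sterome depth with a
  power-law t/D reinforcement gradient declining away from the cuticle;
* Brownian traits on a phylogeny, for null and alternative contrast tests.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point as _Point, Polygon as _ShapelyPolygon

from .fibers import FIBER_COLUMNS
from .geometry import CrossSection, PolygonOutline, TissueRegion
from .mechanics import STANDARD_GRAVITY, TissueModuli
from .phylo import PhyloTree, parse_newick

__all__ = [
    "SyntheticError",
    "SectionSpec",
    "AllometrySpec",
    "generate_cross_section",
    "generate_trait_table",
    "generate_fiber_population",
    "simulate_brownian",
    "random_tree",
    "noise_sigma_for_r2",
    "simulate_sma_pair",
]


class SyntheticError(ValueError):
    """A generator spec is internally inconsistent or geometrically impossible."""


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of an idealized petiole cross-section.

    The sterome is an annulus of radial thickness
    ``sterome_thickness_fraction * outer_radius_mm`` under the cuticle;
    the interior is parenchyma with ``n_bundles`` circular vascular bundles
    (xylem core wrapped in a phloem sheath).  A positive
    ``groove_depth_fraction`` carves an adaxial notch into the outline; the
    groove may not cut past the sterome's inner boundary.  ``pith_eccentricity``
    shifts the bundle cluster dorsally as a fraction of the interior radius.
    """

    outer_radius_mm: float = 1.0
    sterome_thickness_fraction: float = 0.2
    n_bundles: int = 1
    bundle_radius_fraction: float = 0.2  # phloem outer radius / interior radius
    xylem_fraction: float = 0.7  # xylem radius / bundle radius
    groove_depth_fraction: float = 0.0  # of outer radius
    groove_width_fraction: float = 0.25  # of outer radius
    pith_eccentricity: float = 0.0
    n_vertices: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outer_radius_mm > 0:
            raise SyntheticError("outer radius must be positive")
        for name in ("sterome_thickness_fraction", "bundle_radius_fraction", "xylem_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SyntheticError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.groove_depth_fraction < 1:
            raise SyntheticError("groove depth fraction must lie in [0, 1)")
        if self.groove_depth_fraction > 0 and not 0 < self.groove_width_fraction < 1:
            raise SyntheticError("groove width fraction must lie in (0, 1)")
        if self.groove_depth_fraction >= self.sterome_thickness_fraction:
            raise SyntheticError(
                "groove would cut past the sterome's inner boundary "
                f"(depth {self.groove_depth_fraction} >= thickness fraction "
                f"{self.sterome_thickness_fraction})"
            )
        if not -1 < self.pith_eccentricity < 1:
            raise SyntheticError("pith eccentricity must lie in (-1, 1)")
        if self.n_bundles < 0:
            raise SyntheticError("bundle count cannot be negative")
        if self.n_vertices < 16:
            raise SyntheticError("need at least 16 vertices per circle")

    @classmethod
    def from_area_fractions(
        cls,
        sterome_area_fraction: float,
        bundle_area_fraction: float = 0.05,
        outer_radius_mm: float = 1.0,
        **kwargs,
    ) -> "SectionSpec":
        """Spec whose sterome annulus occupies a given fraction of section
        *area* and whose single central bundle occupies ``bundle_area_fraction``."""
        if not 0 < sterome_area_fraction < 1:
            raise SyntheticError("sterome area fraction must lie in (0, 1)")
        thickness_fraction = 1.0 - math.sqrt(1.0 - sterome_area_fraction)
        interior_fraction = math.sqrt(1.0 - sterome_area_fraction)
        if not 0 < bundle_area_fraction < interior_fraction**2:
            raise SyntheticError("bundle area fraction leaves no parenchyma")
        bundle_radius_fraction = math.sqrt(bundle_area_fraction) / interior_fraction
        return cls(
            outer_radius_mm=outer_radius_mm,
            sterome_thickness_fraction=thickness_fraction,
            bundle_radius_fraction=bundle_radius_fraction,
            **kwargs,
        )


def _circle(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def generate_cross_section(spec: SectionSpec) -> CrossSection:
    """Build the idealized cross-section described by ``spec``.

    Deterministic: the same spec (including seed) yields identical vertex
    lists.  With no groove and no bundles the result reduces to the analytic
    annulus-over-disc fixture.
    """
    R = spec.outer_radius_mm
    Ri = R * (1.0 - spec.sterome_thickness_fraction)
    n = spec.n_vertices

    outer_vertices = _circle(0.0, 0.0, R, n)
    if spec.groove_depth_fraction > 0:
        depth = spec.groove_depth_fraction * R
        half_width = 0.5 * spec.groove_width_fraction * R
        # carve a disc whose lowest point sits `depth` below the dorsal rim
        groove_r = max(half_width, depth)
        groove_center_y = R - depth + groove_r
        groove = _Point(0.0, groove_center_y).buffer(groove_r, quad_segs=max(16, n // 8))
        carved = _ShapelyPolygon(outer_vertices).difference(groove)
        if carved.geom_type != "Polygon":
            raise SyntheticError("groove split the outline into pieces")
        outer_vertices = np.asarray(carved.exterior.coords)[:-1]

    sterome = TissueRegion(
        "sclerenchyma",
        PolygonOutline(outer_vertices, label="sterome outer"),
        holes=[PolygonOutline(_circle(0.0, 0.0, Ri, n), label="sterome inner")],
    )

    regions = [sterome]
    bundle_holes: list[PolygonOutline] = []
    if spec.n_bundles > 0:
        rb = spec.bundle_radius_fraction * Ri  # phloem outer radius
        rx = spec.xylem_fraction * rb
        pith_y = spec.pith_eccentricity * Ri
        if spec.n_bundles == 1:
            centers = [(0.0, pith_y)]
        else:
            ring = 0.45 * Ri
            ang = np.linspace(0.0, 2.0 * math.pi, spec.n_bundles, endpoint=False)
            centers = [(ring * math.cos(a), pith_y + ring * math.sin(a)) for a in ang]
        nb = max(96, n // 4)
        for k, (bx, by) in enumerate(centers):
            if math.hypot(bx, by) + rb >= Ri:
                raise SyntheticError(
                    f"bundle {k} (center ({bx:.3g}, {by:.3g}), radius {rb:.3g}) "
                    "does not fit inside the parenchyma interior"
                )
            phloem_outer = PolygonOutline(_circle(bx, by, rb, nb), label=f"bundle {k} phloem")
            xylem_outer = PolygonOutline(_circle(bx, by, rx, nb), label=f"bundle {k} xylem")
            regions.append(TissueRegion("phloem", phloem_outer, holes=[xylem_outer]))
            regions.append(TissueRegion("xylem", xylem_outer))
            bundle_holes.append(phloem_outer)

    parenchyma = TissueRegion(
        "parenchyma",
        PolygonOutline(_circle(0.0, 0.0, Ri, n), label="parenchyma outer"),
        holes=bundle_holes,
    )
    regions.insert(1, parenchyma)
    return CrossSection(regions)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


def noise_sigma_for_r2(slope: float, sx: float, r2: float) -> float:
    """Log-scale noise SD giving expected R^2 ``r2`` for a power law of
    ``slope`` when the log-x values have SD ``sx``.

    From R^2 = b^2 sx^2 / (b^2 sx^2 + sigma^2).
    """
    if not 0 < r2 <= 1:
        raise SyntheticError("target R^2 must lie in (0, 1]")
    return abs(slope) * sx * math.sqrt((1.0 - r2) / r2)


@dataclass(frozen=True)
class AllometrySpec:
    """Power-law trait table spec: n species over a stipe-diameter range.

    The primary relation is leaf area = a * d^b with lognormal noise (sigma
    on the log10 scale); secondary traits follow their own documented power
    laws off stipe diameter so every pipeline column is filled consistently.
    Defaults emulate the observed ranges: diameters 0.45-12.84 mm and leaf
    areas of a few to a few thousand cm^2.
    """

    n_species: int = 21
    slope: float = 2.189
    elevation: float = 1.193  # log10(cm^2) at d = 1 mm
    sigma_log10: float = 0.12
    diameter_range_mm: tuple[float, float] = (0.45, 12.84)
    #: None -> sterome area fraction drawn per species, uniform over
    #: ``sterome_fraction_range`` and independent of stipe diameter (the
    #: sterome *fraction* carries no size signal, unlike its thickness)
    sterome_area_fraction: float | None = None
    sterome_fraction_range: tuple[float, float] = (0.1, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise SyntheticError("need at least 3 species")
        if self.sigma_log10 < 0:
            raise SyntheticError("noise sigma cannot be negative")
        lo, hi = self.diameter_range_mm
        if not 0 < lo < hi:
            raise SyntheticError("diameter range must be 0 < lo < hi")
        if self.sterome_area_fraction is not None and not 0 < self.sterome_area_fraction < 1:
            raise SyntheticError("sterome area fraction must lie in (0, 1)")
        flo, fhi = self.sterome_fraction_range
        if not 0 < flo <= fhi < 1:
            raise SyntheticError("sterome fraction range must satisfy 0 < lo <= hi < 1")


def _concentric_moments(d_mm: float, sterome_area_fraction: float) -> dict[str, float]:
    """Analytic per-tissue I_x (mm^4) of the concentric circular idealization
    with a 5%-area central vascular core (2.5% xylem, 2.5% phloem)."""
    r = d_mm / 2.0
    r_in = r * math.sqrt(1.0 - sterome_area_fraction)  # sterome inner radius
    r_ph = r * math.sqrt(0.05)  # phloem sheath outer radius
    r_xy = r * math.sqrt(0.025)  # xylem core radius
    quarter_pi = math.pi / 4.0
    return {
        "sclerenchyma": quarter_pi * (r**4 - r_in**4),
        "parenchyma": quarter_pi * (r_in**4 - r_ph**4),
        "phloem": quarter_pi * (r_ph**4 - r_xy**4),
        "xylem": quarter_pi * r_xy**4,
    }


def generate_trait_table(spec: AllometrySpec) -> pd.DataFrame:
    """Generate a species trait table with consistent mechanical columns.

    Stipe diameters are log-uniform over the spec range.  Leaf area follows
    the spec's primary power law; leaf length, sterome thickness, SLA, lumen
    diameter and t/D follow secondary power laws with proportionally scaled
    noise.  I comes from the circular idealization (pi d^4 / 64), EI from the
    concentric-annulus tissue split under the default moduli, and the
    buckling columns from the Euler criterion.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    lo, hi = spec.diameter_range_mm
    d_mm = 10 ** rng.uniform(math.log10(lo), math.log10(hi), n)
    d_mm = np.sort(d_mm)
    logd = np.log10(d_mm)

    def power(elev: float, slope: float, sigma_scale: float = 1.0) -> np.ndarray:
        eps = rng.normal(0.0, spec.sigma_log10 * sigma_scale, n)
        return 10 ** (elev + slope * logd + eps)

    leaf_area_cm2 = power(spec.elevation, spec.slope)
    leaf_length_m = power(-0.80, 1.0445)
    # durable low-SLA leaves on thick-stiped species, noisy
    sla_cm2_g = power(2.35, -0.25, sigma_scale=0.8)
    leaf_mass_g = leaf_area_cm2 / sla_cm2_g
    sterome_thickness_um = power(1.85, 0.672)
    petiole_length_m = 0.45 * leaf_length_m * 10 ** rng.normal(0.0, 0.05, n)
    lumen_diameter_um = 0.2656 * sterome_thickness_um**0.683
    tD = 51.4 * sterome_thickness_um**-0.952
    t_um = tD * lumen_diameter_um
    lumen_area = math.pi * (lumen_diameter_um / 2.0) ** 2
    wall_area = math.pi * ((lumen_diameter_um / 2.0 + t_um) ** 2 - (lumen_diameter_um / 2.0) ** 2)
    fwf = wall_area / (lumen_area + wall_area)

    if spec.sterome_area_fraction is None:
        fractions = rng.uniform(*spec.sterome_fraction_range, n)
    else:
        fractions = np.full(n, spec.sterome_area_fraction)

    moduli = TissueModuli()
    i_mm4 = math.pi * d_mm**4 / 64.0
    ei_nm2 = np.empty(n)
    pct_scler = np.empty(n)
    pct_i_scler = np.empty(n)
    pct_par = np.empty(n)
    pct_i_par = np.empty(n)
    for k in range(n):
        per_tissue = _concentric_moments(float(d_mm[k]), float(fractions[k]))
        total_i = sum(per_tissue.values())
        ei = sum(moduli[t] * i for t, i in per_tissue.items()) * 1e-6
        ei_nm2[k] = ei
        pct_scler[k] = 100.0 * fractions[k]
        pct_i_scler[k] = 100.0 * per_tissue["sclerenchyma"] / total_i
        pct_par[k] = 100.0 * (0.95 - fractions[k])
        pct_i_par[k] = 100.0 * per_tissue["parenchyma"] / total_i

    g = STANDARD_GRAVITY
    f_n = leaf_mass_g / 1000.0 * g
    l_max_m = np.sqrt(math.pi**2 * ei_nm2 / (4.0 * f_n))
    safety = l_max_m / petiole_length_m

    return pd.DataFrame(
        {
            "species": [f"sp{k:02d}" for k in range(n)],
            "stipe_diameter_mm": d_mm,
            "leaf_length_m": leaf_length_m,
            "leaf_area_cm2": leaf_area_cm2,
            "leaf_mass_g": leaf_mass_g,
            "sterome_thickness_um": sterome_thickness_um,
            "petiole_length_m": petiole_length_m,
            "SLA_cm2_g": sla_cm2_g,
            "lumen_diameter_um": lumen_diameter_um,
            "tD": tD,
            "FWF": fwf,
            "I_mm4": i_mm4,
            "EI_Nm2": ei_nm2,
            "pct_sclerenchyma": pct_scler,
            "pct_I_sclerenchyma": pct_i_scler,
            "pct_parenchyma": pct_par,
            "pct_I_parenchyma": pct_i_par,
            "F_N": f_n,
            "L_max_m": l_max_m,
            "safety_factor": safety,
        }
    )


def simulate_sma_pair(
    n: int,
    slope: float,
    elevation: float,
    r2: float,
    seed: int,
    symmetric_errors: bool = True,
    latent_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a positive trait pair whose log-log SMA has the given slope
    and expected R^2.

    With ``symmetric_errors`` (the SMA error model) a latent log-scale
    variable u carries the signal and both variables receive independent
    errors whose SD ratio equals |slope|, the regime in which the SMA slope
    estimator is consistent.  Otherwise all noise goes into y (the
    ordinary power-law-plus-noise model).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, latent_sd, n)
    if symmetric_errors:
        # r = sqrt(R^2) = var_u / (var_u + var_e)
        r = math.sqrt(r2)
        sigma_e = latent_sd * math.sqrt(1.0 / r - 1.0)
        lx = u + rng.normal(0.0, sigma_e, n)
        ly = elevation + slope * u + rng.normal(0.0, abs(slope) * sigma_e, n)
    else:
        sigma = noise_sigma_for_r2(slope, latent_sd, r2)
        lx = u
        ly = elevation + slope * u + rng.normal(0.0, sigma, n)
    return 10.0**lx, 10.0**ly


# ---------------------------------------------------------------------------
# fiber populations
# ---------------------------------------------------------------------------


def generate_fiber_population(
    n_cells: int,
    sterome_thickness_um: float = 120.0,
    gradient_exponent: float = -0.627,
    gradient_coefficient: float = 10.0,
    noise_sigma_log10: float = 0.0,
    wall_thickness_um: float = 3.0,
    n_leaves: int = 3,
    species: str = "synthetic",
    seed: int = 0,
) -> pd.DataFrame:
    """Fiber cells through the sterome depth with a t/D power-law gradient.

    Distances to the cuticle are uniform through the sterome; each cell's
    reinforcement is t/D = c * distance^exponent with multiplicative
    lognormal noise.  Wall thickness is held near ``wall_thickness_um`` (with
    a thin/thick split) and the lumen diameter is back-solved from t/D, so
    every generated row is mutually consistent with the per-cell metric
    formulas.
    """
    if n_cells < 1:
        raise SyntheticError("need at least one cell")
    if sterome_thickness_um <= 0 or wall_thickness_um <= 0:
        raise SyntheticError("thicknesses must be positive")
    rng = np.random.default_rng(seed)
    distance = rng.uniform(0.05 * sterome_thickness_um, sterome_thickness_um, n_cells)
    eps = rng.normal(0.0, noise_sigma_log10, n_cells)
    t_over_d = gradient_coefficient * distance**gradient_exponent * 10.0**eps
    t = np.full(n_cells, wall_thickness_um)
    d = t / t_over_d
    lumen_area = math.pi * (d / 2.0) ** 2
    delta = rng.uniform(0.0, 0.3 * wall_thickness_um, n_cells)
    sectors = np.array(["adaxial", "abaxial", "lateral"])[np.arange(n_cells) % 3]
    leaves = np.array([f"L{k % n_leaves + 1}" for k in range(n_cells)])
    return pd.DataFrame(
        {
            "species": species,
            "leaf": leaves,
            "sector": sectors,
            "lumen_area_um2": lumen_area,
            "wall_thin_um": t - delta,
            "wall_thick_um": t + delta,
            "distance_um": distance,
        },
        columns=list(FIBER_COLUMNS),
    )


# ---------------------------------------------------------------------------
# trait evolution on trees
# ---------------------------------------------------------------------------


def simulate_brownian(
    tree: PhyloTree, rate: float, root_value: float = 0.0, seed: int = 0
) -> dict[str, float]:
    """Brownian-motion trait values at the tips of ``tree``.

    Along each edge the trait accrues an independent Gaussian increment with
    variance ``rate * branch_length``.
    """
    if rate < 0:
        raise SyntheticError("Brownian rate cannot be negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, math.sqrt(rate * bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def random_tree(n_tips: int, seed: int = 0, mean_branch_length: float = 1.0) -> PhyloTree:
    """Random binary rooted tree (birth-death-free coalescent-style shape)
    with exponential branch lengths; tips labeled t1..tn."""
    if n_tips < 2:
        raise SyntheticError("need at least two tips")
    rng = np.random.default_rng(seed)
    nodes = [f"t{i + 1}:{rng.exponential(mean_branch_length):.9g}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        bl = rng.exponential(mean_branch_length)
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        if rest:
            merged = f"{merged}:{bl:.9g}"
        nodes = rest + [merged]
    return parse_newick(nodes[0] + ";")
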