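# Methods

## The model

A fern petiole is treated as a straight, prismatic composite beam whose
cross-section is partitioned into four tissues: sclerenchyma (the
hypodermal sterome), ground parenchyma, and the xylem and phloem of the
vascular bundles. Each tissue contributes geometry (its axial second moment
of area, I) and an attributed material stiffness (Young's modulus, E).
Three idealizations follow from this frame and bound what the outputs mean:

* *Prismatic beam* — EI is taken as constant along the petiole; sections are
  sampled mid-stipe, so basal taper is ignored. This biases Euler lengths
  slightly downward for tapered petioles.
* *Attributed moduli* — the tissue moduli are fixed reference values for
  hydrated tissues (MN m⁻²): sclerenchyma 22 555.3, primary xylem 837.49,
  phloem and parenchyma 18.73. Species-specific tissue testing is outside
  scope; all rigidity values are therefore *theoretical* (EI_theor), useful
  comparatively rather than as absolute measurements.
* *Plane sections* — tissues are assumed perfectly bonded, so rigidities add:
  EI_theor = Σᵢ Eᵢ Iᵢ.

## Section geometry

Outlines are simple polygons (≥3 vertices, no self-intersection, nonzero
area), optionally with holes; either winding order is accepted and
normalized counter-clockwise on ingest. Area, centroid and second moments
come from the per-edge closed forms of Green's theorem evaluated on the
vertex list — exact for the polygon, resolution-free, and fast. A
rasterized grid integration exists only in the test suite as an independent
oracle.

Per-tissue moments are referred to x- and y-parallel neutral axes through
the **area centroid of the whole section** ("center of mass" of the section
in the sense of uniform density). The alternative — a modulus-weighted
centroid, which is where the true neutral axis of a composite beam lies —
was considered and deliberately not used for the headline outputs: with the
sterome dominating EI by three orders of magnitude the two centroids are
nearly coincident for realistic sections, and the area centroid keeps the
geometric quantities (I, tissue shares of I) independent of the moduli
configuration. I_x denotes the moment about the horizontal axis (resisting
bending in the vertical, dorso-ventral plane), I_y about the vertical axis.
The product moment I_xy is computed and reported for completeness but feeds
no downstream equation.

Adaxial grooves are represented as boundary concavity of the outline, not
as holes: a groove is open to the exterior, so treating it as a hole would
misplace the centroid.

Conventions and tolerances:

* lengths mm, areas mm², moments mm⁴ inside the geometry module; the
  mechanics module reconciles units (mm⁴ × MN m⁻² × 10⁻⁶ = N m²);
* regions of different tissues may overlap by at most 10⁻⁶ of section area
  (hand-drawn outlines abut imperfectly); larger overlaps are rejected with
  the tissue pair named;
* circles and ellipses in fixtures are 512-gons, which underestimates I by
  under 0.03 % (inscribed-polygon bias, monotone in vertex count).

## Mechanics

EI_theor, per-tissue contributions (Eᵢ Iᵢ / EI_theor) and the composite
modulus E_composite = EI_theor / I_total are computed for both bending
planes. Euler buckling uses the fixed-free column limit,
L_max = (π² EI / 4F)^½, with F the lamina dry weight (mass × g,
g = 9.81 m s⁻² by default and configurable). The petiole's own mass is
excluded from F by default — consistent with how leaf loads were measured —
with an optional `petiole_mass` argument for sensitivity analysis. The
safety factor is L_max / L_petiole.

The rigidity entering the buckling criterion defaults to the vertical-plane
value EI_x (load from above: rain, debris, the lamina itself); this is a
config knob (`buckling_axis`) because the choice is a modeling decision,
not a law. The ratio EI_x/EI_y is reported with its definition in the
output metadata, since "x" and "y" conventions vary across the literature.

## Fiber morphometrics

Raw per-cell measurements are lumen area (μm²), the thinnest and thickest
single-wall readings (μm), and distance to the cuticle (μm). Derived
metrics: D = 2√(A/π) (area-equivalent circle), t = mean of the two wall
readings, reinforcement t/D, and the fiber wall fraction
FWF = wall / (lumen + wall) with the wall modeled as a **concentric annulus
of radial thickness t** around the lumen circle (a single wall, not the
shared double wall). The annulus model is isolated in one function
(`wall_area_annulus`) so alternative wall-area geometries (e.g. t ×
perimeter) can be swapped; its inverse (`wall_thickness_for_fwf`) maps the
observed (D, FWF) extremes — (3.52 μm, 0.93) and (17.61 μm, 0.50) — onto
wall thicknesses of 4.9 and 3.6 μm, inside the plausible measured range,
which is the check that motivated this choice.

Sterome thickness aggregates in two stages exactly as measured: sector
values (adaxial/abaxial/lateral) → leaf mean → species mean, with SD over
leaf means. Two-stage averaging is not the pooled mean when sector counts
differ between leaves; both the tests and the API treat the two-stage value
as the definition. Two leaves per species are accepted (some species could
only be sampled twice).

The radial reinforcement profile fits log₁₀(t/D) against log₁₀(distance)
by SMA, pooled across species (per-species grouping is available in the
returned table); a flat profile is flagged degenerate rather than fitted.

## Allometry

All trait pairs are fitted log-log by standardized major axis:
|b| = s_y/s_x with the sign of r, elevation = ȳ − b x̄, p from the test of
r = 0, adjusted R² from r², and Warton-style F-based slope confidence
intervals. SMA is used because both traits carry error; its slope estimator
is consistent when the error-variance ratio matches b² (the symmetric-error
regime the simulators reproduce), and is biased upward by 1/√R² when all
noise sits in y — the tests cover both regimes.

Log base 10 is the default and is recorded in every fit, because elevations
are only meaningful under a stated base and unit convention. Units follow
the trait-table column names (mm, m, cm², g, μm); anyone comparing
elevations against other work must reconcile units first. p-values are
reported per fit without multiple-testing correction; the scaling table is
a descriptive panel, not a family of confirmatory tests.

## Phylogenetic contrasts

Felsenstein's recursion runs post-order on the rooted tree: contrast
(x_l − x_r)/√(v_l + v_r), ancestral value the variance-weighted mean,
parent branch extended by v_l v_r/(v_l + v_r). Contrast signs are
arbitrary, so trait association uses regression **through the origin** of
y-contrasts on x-contrasts (n − 1 error df), which is sign-invariant and —
as the test suite verifies to 10⁻⁹ against direct covariance inversion —
identical to the Brownian phylogenetic GLS slope. Species with missing
trait values are pruned (degree-2 nodes suppressed, branch lengths summed)
before contrasts are computed, and every pruning is logged.

Polytomies are resolved to arbitrary binary nodes with zero-length
branches; zero-length branches are floored at 10⁻⁸ × tree height for the
variance arithmetic. Branch lengths are used as given (no rate rescaling).

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, at the scale of the real study system:

* **Sections** — sterome annulus of configurable thickness fraction,
  parenchyma interior, circular vascular bundles (xylem core at 70 % of the
  bundle radius, phloem sheath), optional adaxial groove carved from the
  outline (constrained not to cut past the sterome's inner boundary),
  optional pith eccentricity. Real steles are lobed rather than circular,
  but vascular tissue carries well under 15 % of I, so bundle shape
  fidelity is immaterial for rigidity conclusions.
* **Trait tables** — stipe diameters log-uniform over 0.45–12.84 mm (the
  observed range); leaf area follows a/d^b with defaults b = 2.189,
  log₁₀ a = 1.193 (cm² vs mm); secondary traits (leaf length, sterome
  thickness, SLA, lumen diameter, t/D) follow their own power laws with
  elevations chosen once to land in realistic ranges (e.g. steromes of
  ~40 μm on the narrowest stipes, ~400 μm on the widest). Noise is
  lognormal — additive Gaussian on the log scale, σ = 0.12 log₁₀ units by
  default — because all fits are log-log; `noise_sigma_for_r2` gives the
  closed-form σ for a target R². The sterome *area fraction* is drawn
  uniform over 0.1–0.6 independent of diameter (it carries no size signal,
  unlike sterome thickness). Mechanical columns (I, EI, L_max, safety
  factor) are filled from the circular idealization and the default moduli,
  so every derived column is internally consistent.
* **Fiber populations** — distances uniform through the sterome depth,
  t/D = c·distance^g (default g = −0.627, c = 10) with lognormal noise;
  wall thickness held near 3 μm with a thin/thick split and lumen diameter
  back-solved from t/D, so generated rows satisfy the fiber invariants by
  construction.
* **Brownian traits** — independent Gaussian increments with variance
  rate × branch length along each edge; used for contrast nulls and
  power checks.

What passing tests on these inputs do **not** show: robustness to
segmentation error in real outlines, to non-lognormal trait noise, to
lobed steles, or to within-species variance structure — synthetic species
are exchangeable draws, real ones are not.

## Problem sizes and numerical choices

The test suite and the demo pipeline run on deliberately modest sizes that
still pin down the statistics: 512-gon sections for analytic comparisons
(128–256 where many sections are built), 2000×2000 grids for the
rasterized oracle, 200 simulated 21-species tables for SMA slope recovery,
1000 replicates on a 64-tip tree for the contrast null calibration, and
trees of ≤6 tips for the exact PIC–GLS identity. Degenerate inputs fail
loudly and early: zero-area or self-intersecting outlines, constant
vectors, all-missing trait pairs, unknown config keys, duplicate tips.

## Known limitations

* Torsion, tapered or curved beams, and dynamic (wind) loading are out of
  scope; the buckling model is the static fixed-free Euler limit.
* Attributed moduli make all EI values comparative, not absolute; lignified
  parenchyma — present in several small desert-adapted species and likely
  stiffer than ordinary parenchyma — is not modeled, so their rigidity is
  underestimated.
* SMA slope-heterogeneity tests between clades and major-axis variants are
  not implemented.
* Image segmentation is upstream of this package: outlines arrive already
  digitized.
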