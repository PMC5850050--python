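# sterome

Petiole biomechanics and comparative morphometrics for ferns.

Most ferns stiffen their leaf stalks (petioles, or stipes) with a *sterome*:
a hypodermal cylinder of sclerenchyma fibers just beneath the cuticle.
`sterome` implements the quantitative machinery needed to study this tissue
comparatively across species:

* **Section geometry** — exact area, centroid and axial second moments of
  area (I, mm⁴) of digitized tissue outlines (sclerenchyma, parenchyma,
  xylem, phloem), computed with per-edge Green's-theorem closed forms on the
  polygon vertices. Per-tissue moments are referred to neutral axes through
  the whole-section area centroid, so they are additive:
  `I_total = Σᵢ Iᵢ`.
* **Composite-beam mechanics** — theoretical flexural rigidity
  `EI_theor = Σᵢ Eᵢ Iᵢ` (N m²) from attributed tissue moduli
  (E_sclerenchyma = 22 555.3, E_xylem = 837.49,
  E_phloem = E_parenchyma = 18.73 MN m⁻²), per-tissue fractional
  contributions, the composite modulus `E_composite = EI/I`, and Euler
  buckling: `L_max = (π² EI / 4F)^½` with safety factor
  `L_max / L_petiole`.
* **Fiber morphometrics** — area-equivalent lumen diameter
  `D = 2√(A/π)`, single-wall thickness t, the reinforcement ratio t/D, the
  fiber wall fraction (FWF, from a concentric-annulus wall model), and
  two-stage sterome-thickness aggregation (sectors → leaf → species).
* **Allometry** — standardized major axis (SMA) regression on log₁₀-log₁₀
  trait pairs (`slope = sign(r)·s_y/s_x`) with Shapiro–Wilk normality
  screening, for trait tables spanning stipe diameter, leaf size, sterome
  traits and mechanical quantities.
* **Phylogenetic contrasts** — Felsenstein's independent contrasts on
  rooted Newick trees (with tip pruning for missing data) and through-origin
  contrast regression, equivalent to Brownian-motion phylogenetic GLS.
* **Synthetic data** — generators for idealized cross-sections (sterome
  annulus, vascular bundles, optional adaxial groove), power-law trait
  tables, fiber populations with a radial reinforcement gradient, and
  Brownian traits on trees; these drive the test suite and demo pipeline.

## Worked example

An idealized mid-stipe cross-section of 1 mm outer radius whose sterome
occupies the outer 20 % of the radius, with one central vascular bundle,
loaded by a 10 g lamina on a 45.8 mm petiole:

```python
from sterome import *

spec = SectionSpec(outer_radius_mm=1.0, sterome_thickness_fraction=0.2,
                   n_bundles=1, bundle_radius_fraction=0.2)
section = generate_cross_section(spec)
moments = tissue_moments(section)
profile = flexural_rigidity(moments)
res = buckling_analysis(ei=profile.ei["x"], dry_mass=0.010, l_petiole=0.0458)
```

prints (see `scripts/` and the CLI for file-based workflows):

```
I_x total     = 0.7854 mm^4
  I_x sclerenchyma = 0.463676 mm^4  (contribution 0.9994)
  I_x parenchyma   = 0.321169 mm^4  (contribution 0.0006)
  I_x phloem       = 0.000391 mm^4  (contribution 0.0000)
  I_x xylem        = 0.000123 mm^4  (contribution 0.0000)
EI_x          = 0.010464 N m^2
E_composite   = 13324 MN m^-2
L_max         = 0.513 m
safety factor = 11.2
```

Reading the output: the full disc has `I = π r⁴/4 ≈ 0.7854 mm⁴`, of which
the sterome annulus carries 0.4637 mm⁴ — but because sclerenchyma is over a
thousand times stiffer than parenchyma, it supplies 99.94 % of the flexural
rigidity. The section could hold its 10 g load on a petiole up to 0.513 m
long before Euler buckling; at 45.8 mm it is overbuilt by a factor of 11.

## Command line

```sh
sterome simulate --out demo --seed 1        # synthetic input bundle
sterome run demo --out demo-results         # full pipeline
sterome report demo-results                 # plain-text summary
sterome moments demo/sections/sp00_1.xsec.json
sterome buckling --ei 0.010465 --mass 0.010 --petiole-length 0.0458
```

`sterome run` writes per-specimen mechanics, buckling results, fiber
summaries and the SMA scaling table with PIC columns, each CSV paired with a
`.meta.json` sidecar recording units, conventions and the config hash.
Moduli and pipeline options live in a TOML config (`[moduli]`,
`[pipeline]`); unknown keys are rejected.

## Documentation

`docs/methods.md` describes the model assumptions, unit conventions, the
synthetic generators and their limits, and the numerical choices.
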