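"""Composite-beam mechanics of the petiole.

The petiole is modeled as a composite beam of four tissues, each attributed a
Young's modulus (MN m^-2, hydrated tissue values measured on *Psilotum
nudum*).  With per-tissue second moments of area I_i (mm^4) about the section
centroidal axes, the theoretical flexural rigidity is

    EI_theor = sum_i E_i * I_i        (N m^2, after unit reconciliation)

the fractional contribution of tissue i is E_i I_i / EI_theor, and the
composite (structural) modulus is E_composite = EI_theor / I_total.

Euler buckling of the petiole under the lamina's weight F gives the maximum
sustainable petiole length

    L_max = (pi^2 * EI / (4 F)) ** 0.5

and the safety factor from buckling is L_max / L_petiole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import SectionMoments

__all__ = [
    "MechanicsError",
    "TissueModuli",
    "MechanicalProfile",
    "BucklingResult",
    "flexural_rigidity",
    "leaf_load",
    "euler_max_length",
    "buckling_safety",
    "buckling_analysis",
    "MM4_TO_M4",
    "STANDARD_GRAVITY",
]

#: mm^4 -> m^4
MM4_TO_M4 = 1e-12
#: default gravitational acceleration, m s^-2
STANDARD_GRAVITY = 9.81


class MechanicsError(ValueError):
    """Invalid input to a mechanics computation."""


@dataclass(frozen=True)
class TissueModuli:
    """Attributed Young's moduli per tissue, MN m^-2 (hydrated).

    Defaults are the *Psilotum nudum* tissue moduli used throughout the
    composite-rigidity model.
    """

    sclerenchyma: float = 22555.3
    xylem: float = 837.49
    phloem: float = 18.73
    parenchyma: float = 18.73

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not value > 0:
                raise MechanicsError(f"modulus for {name} must be positive, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "sclerenchyma": self.sclerenchyma,
            "xylem": self.xylem,
            "phloem": self.phloem,
            "parenchyma": self.parenchyma,
        }

    def __getitem__(self, tissue: str) -> float:
        try:
            return self.as_dict()[tissue]
        except KeyError:
            raise MechanicsError(
                f"no Young's modulus attributed to tissue {tissue!r}"
            ) from None


@dataclass(frozen=True)
class MechanicalProfile:
    """Flexural rigidity profile of one petiole cross-section.

    ``ei`` maps axis ('x' = about the horizontal axis, i.e. bending in the
    vertical plane; 'y' = about the vertical axis) to EI_theor in N m^2.
    ``contributions`` holds each tissue's dimensionless fraction of EI per
    axis; ``e_composite`` is EI/I per axis in MN m^-2.  ``ei_ratio`` is
    EI_x / EI_y under this axis convention: a ratio below 1 means the section
    is stiffer about the vertical axis than about the horizontal one.
    """

    ei: dict[str, float]
    contributions: dict[str, dict[str, float]]
    e_composite: dict[str, float]
    moments: SectionMoments

    @property
    def ei_ratio(self) -> float:
        return self.ei["x"] / self.ei["y"]


@dataclass(frozen=True)
class BucklingResult:
    """Euler-buckling summary for one petiole under a lamina load."""

    force: float  # N
    l_max: float  # m
    l_petiole: float  # m
    safety_factor: float  # dimensionless, = l_max / l_petiole


def flexural_rigidity(moments: SectionMoments, moduli: TissueModuli | None = None) -> MechanicalProfile:
    """Theoretical flexural rigidity of a composite section, both axes.

    Per-tissue I (mm^4) times attributed E (MN m^-2) gives EI in
    mm^4 * MN m^-2 = 1e-6 N m^2, summed over tissues.  Contributions are the
    per-tissue fractions of that sum; E_composite = EI / I_total in MN m^-2.
    """
    moduli = moduli or TissueModuli()
    ei: dict[str, float] = {}
    contributions: dict[str, dict[str, float]] = {}
    e_composite: dict[str, float] = {}
    per_axis_i = {"x": moments.i_x, "y": moments.i_y}
    for axis, i_map in per_axis_i.items():
        terms = {t: moduli[t] * i_t for t, i_t in i_map.items()}
        total = sum(terms.values())  # mm^4 * MN m^-2
        if total <= 0:
            raise MechanicsError(f"non-positive EI about axis {axis}")
        ei[axis] = total * 1e-6  # N m^2
        contributions[axis] = {t: v / total for t, v in terms.items()}
        i_total = sum(i_map.values())
        e_composite[axis] = total / i_total  # MN m^-2
    return MechanicalProfile(
        ei=ei, contributions=contributions, e_composite=e_composite, moments=moments
    )


def leaf_load(dry_mass: float, g: float = STANDARD_GRAVITY) -> float:
    """Weight (N) of a lamina of ``dry_mass`` kg under gravity ``g``."""
    if not dry_mass > 0:
        raise MechanicsError(f"dry mass must be positive, got {dry_mass}")
    if not g > 0:
        raise MechanicsError(f"gravitational acceleration must be positive, got {g}")
    return dry_mass * g


def euler_max_length(ei: float, force: float) -> float:
    """Longest petiole (m) sustaining axial load ``force`` without buckling.

    L_max = (pi^2 EI / (4 F)) ** 0.5 for a column fixed at the base and free
    at the loaded tip.
    """
    if not ei > 0:
        raise MechanicsError(f"EI must be positive, got {ei}")
    if not force > 0:
        raise MechanicsError(f"load must be positive, got {force}")
    return math.sqrt(math.pi**2 * ei / (4.0 * force))


def buckling_safety(l_max: float, l_petiole: float) -> float:
    """Safety factor from buckling, L_max / L_petiole."""
    if not l_max > 0:
        raise MechanicsError(f"L_max must be positive, got {l_max}")
    if not l_petiole > 0:
        raise MechanicsError(f"petiole length must be positive, got {l_petiole}")
    return l_max / l_petiole


def buckling_analysis(
    ei: float,
    dry_mass: float,
    l_petiole: float,
    g: float = STANDARD_GRAVITY,
    petiole_mass: float = 0.0,
) -> BucklingResult:
    """Full buckling summary: load, critical length and safety factor.

    By default the load is the lamina dry mass alone (excluding the petiole's
    own weight); pass ``petiole_mass`` to add it for sensitivity analysis.
    """
    if petiole_mass < 0:
        raise MechanicsError("petiole mass cannot be negative")
    force = leaf_load(dry_mass + petiole_mass, g=g)
    l_max = euler_max_length(ei, force)
    return BucklingResult(
        force=force,
        l_max=l_max,
        l_petiole=l_petiole,
        safety_factor=buckling_safety(l_max, l_petiole),
    )
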