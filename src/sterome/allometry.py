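"""Standardized major axis (SMA) allometry on log-log trait pairs.

Allometric trait relationships of the form y = a x^b are fitted on the
log-transformed scale, where the power law becomes the line
log(y) = b log(x) + log(a).  Because both traits carry measurement and
biological error, the line of best fit is the standardized major axis rather
than ordinary least squares:

    b = sign(r) * s_y / s_x          (slope)
    a = mean(y') - b * mean(x')      (elevation, on the transformed scale)

where s are sample SDs of the transformed variables and r the Pearson
correlation.  The p-value is the test of r = 0 and the adjusted R^2 derives
from r^2.  Confidence intervals for the slope follow Warton et al.'s
F-statistic construction (the one used by the smatr routine).

Variables are screened for normality with the Shapiro-Wilk test; skewed
traits are log-transformed before fitting (log base 10 throughout, recorded
in every fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometryError",
    "DegenerateFitError",
    "NormalityScreen",
    "SMAFit",
    "normality_screen",
    "sma_fit",
    "scaling_table",
    "DEFAULT_PAIRS",
]


class AllometryError(ValueError):
    """Invalid input to an allometric fit."""


class DegenerateFitError(AllometryError):
    """The trait pair carries no detectable linear relationship (r = 0)."""


@dataclass(frozen=True)
class NormalityScreen:
    """Shapiro-Wilk screen of one trait vector."""

    statistic: float
    pvalue: float
    transform_recommended: bool  # True when p < alpha (reject normality)
    alpha: float = 0.05


@dataclass(frozen=True)
class SMAFit:
    """A standardized major axis fit on the (possibly log) transformed scale.

    ``slope`` and ``elevation`` parameterize y' = slope * x' + elevation on
    the transformed scale; for log_base 10 this is the b and log10(a) of the
    power law y = a x^b.  ``ci_low``/``ci_high`` bound the slope at 95%.
    """

    slope: float
    elevation: float
    r2_adj: float
    pvalue: float
    n: int
    r: float
    ci_low: float
    ci_high: float
    log_base: float | None = 10.0


def normality_screen(values: Sequence[float], alpha: float = 0.05) -> NormalityScreen:
    """Shapiro-Wilk normality test with a log-transform recommendation.

    Rejecting normality (p < alpha) recommends log-transforming the trait
    before regression.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise AllometryError("normality screen needs a 1-D vector with n >= 3")
    if np.ptp(v) == 0:
        raise AllometryError("normality screen rejects a constant vector")
    w, p = stats.shapiro(v)
    return NormalityScreen(
        statistic=float(w), pvalue=float(p), transform_recommended=bool(p < alpha), alpha=alpha
    )


def sma_fit(
    x: Sequence[float],
    y: Sequence[float],
    log_base: float | None = 10.0,
    names: Sequence[str] | None = None,
) -> SMAFit:
    """Standardized major axis fit of y on x, log-transformed by default.

    Parameters
    ----------
    x, y
        Paired trait values, n >= 3.  Must be strictly positive when a log
        transform is requested.
    log_base
        Base of the log transform applied to both variables before fitting;
        ``None`` fits on the raw scale.
    names
        Optional per-observation labels (species ids) used in diagnostics for
        non-positive values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AllometryError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 3:
        raise AllometryError(f"SMA fit needs n >= 3, got n = {n}")
    if log_base is not None:
        nonpos = (x <= 0) | (y <= 0)
        if np.any(nonpos):
            if names is not None:
                offenders = [str(names[i]) for i in np.flatnonzero(nonpos)]
            else:
                offenders = [f"index {i}" for i in np.flatnonzero(nonpos)]
            raise AllometryError(
                "log transform requires positive values; offending observations: "
                + ", ".join(offenders)
            )
        tx = np.log(x) / np.log(log_base)
        ty = np.log(y) / np.log(log_base)
    else:
        tx, ty = x, y
    sx = tx.std(ddof=1)
    sy = ty.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateFitError("a variable is constant after transformation")
    r = float(np.corrcoef(tx, ty)[0, 1])
    if abs(r) < 1e-12:
        raise DegenerateFitError("no linear relationship (|r| ~ 0): SMA slope sign undefined")
    slope = float(np.sign(r) * sy / sx)
    elevation = float(ty.mean() - slope * tx.mean())
    # p-value from the test of r = 0 (identical to the OLS slope test)
    tstat = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    pvalue = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    r2 = r * r
    r2_adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))
    # Warton-style slope CI: B = F_crit * (1 - r^2) / (n - 2)
    b_term = stats.f.ppf(0.95, 1, n - 2) * (1.0 - r2) / (n - 2)
    lo = slope * (np.sqrt(b_term + 1.0) - np.sqrt(b_term))
    hi = slope * (np.sqrt(b_term + 1.0) + np.sqrt(b_term))
    return SMAFit(
        slope=slope,
        elevation=elevation,
        r2_adj=r2_adj,
        pvalue=pvalue,
        n=n,
        r=r,
        ci_low=float(min(lo, hi)),
        ci_high=float(max(lo, hi)),
        log_base=log_base,
    )


#: Species-level trait pairs mirroring the standard analysis table
#: (x column, y column), all fitted log-log.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("stipe_diameter_mm", "leaf_length_m"),
    ("stipe_diameter_mm", "leaf_area_cm2"),
    ("stipe_diameter_mm", "leaf_mass_g"),
    ("stipe_diameter_mm", "sterome_thickness_um"),
    ("sterome_thickness_um", "leaf_length_m"),
    ("sterome_thickness_um", "leaf_area_cm2"),
    ("sterome_thickness_um", "leaf_mass_g"),
    ("sterome_thickness_um", "tD"),
    ("sterome_thickness_um", "lumen_diameter_um"),
    ("sterome_thickness_um", "FWF"),
    ("pct_sclerenchyma", "pct_I_sclerenchyma"),
    ("pct_parenchyma", "pct_I_parenchyma"),
    ("EI_Nm2", "leaf_area_cm2"),
    ("I_mm4", "leaf_area_cm2"),
    ("petiole_length_m", "EI_Nm2"),
    ("F_N", "EI_Nm2"),
)


def scaling_table(
    traits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    log_base: float | None = 10.0,
) -> pd.DataFrame:
    """SMA fits for a list of trait pairs, complete cases per pair.

    Returns one row per pair with columns ``x, y, n, r, r2_adj, pvalue,
    slope, elevation, ci_low, ci_high``.  Pairs with fewer than three
    complete cases are skipped with a warning rather than failing the whole
    table.
    """
    if "species" not in traits.columns:
        raise AllometryError("trait table needs a 'species' column")
    rows = []
    for xcol, ycol in pairs:
        for col in (xcol, ycol):
            if col not in traits.columns:
                raise AllometryError(f"unknown trait column {col!r}")
        sub = traits[["species", xcol, ycol]].dropna()
        if len(sub) < 3:
            warnings.warn(
                f"pair ({xcol}, {ycol}): only {len(sub)} complete cases, skipped",
                stacklevel=2,
            )
            continue
        try:
            fit = sma_fit(
                sub[xcol].to_numpy(float),
                sub[ycol].to_numpy(float),
                log_base=log_base,
                names=sub["species"].tolist(),
            )
        except DegenerateFitError as exc:
            warnings.warn(f"pair ({xcol}, {ycol}): degenerate fit skipped ({exc})", stacklevel=2)
            continue
        rows.append(
            {
                "x": xcol,
                "y": ycol,
                "n": fit.n,
                "r": fit.r,
                "r2_adj": fit.r2_adj,
                "pvalue": fit.pvalue,
                "slope": fit.slope,
                "elevation": fit.elevation,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
            }
        )
    return pd.DataFrame(rows)
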