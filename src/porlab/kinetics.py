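"""NADPH binding and photoconversion kinetics from spectral ratio observables.

The dark observable is the intensity ratio F648/F635 (no lipids) or F658/F635
(OPT lipids), which grows as the ternary complex forms with increasing NADPH.
The light observable is F Chlide / F Pchlide after 20 s illumination, taken at
the windowed peak maxima (674–695 and 632–655 nm).  Both are fitted with a
modified Michaelis–Menten saturation curve

    y(c) = vmax * c / (KM + c) + a

whose baseline term ``a`` accounts for the nonzero ratio of inactive samples.
KM from the dark ratio (K_M^D) is an NADPH-binding observable; KM from the
light ratio (K_M^L) a kinetic observable.  Both are observable parameters of
the spectra rather than biochemical constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spectra import (
    CHLIDE_WINDOW,
    PCHLIDE_WINDOW,
    Spectrum,
    average_replicates,
    intensity_at,
    normalize,
    peak_maximum,
)

#: dark-ratio wavelengths (numerator, denominator) by lipid context (nm)
DARK_RATIO_NM = {"none": (648.0, 635.0), "OPT": (658.0, 635.0)}


class RatioError(ValueError):
    """Raised when a ratio observable is undefined (non-positive denominator)."""


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration/ratio points of one titration observable."""

    concentrations: np.ndarray
    values: np.ndarray
    kind: Literal["dark_ratio", "light_ratio"] = "dark_ratio"
    isoform: str = ""
    lipid: str = "none"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and values must be equal-length 1-D")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.all(np.isfinite(y)):
            raise ValueError("ratio values must be finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "values", y)


@dataclass(frozen=True)
class MMFit:
    """Result of a modified Michaelis–Menten fit."""

    vmax: float
    km: float
    a: float
    vmax_se: float
    km_se: float
    a_se: float
    converged: bool
    rss: float
    n: int


def mm_curve(c, vmax, km, a):
    """Hyperbolic saturation with baseline: vmax*c/(km + c) + a."""
    c = np.asarray(c, dtype=float)
    return vmax * c / (km + c) + a


def mm_curve_literal(c, vmax, km, a):
    """The literally printed form vmax*c/(km*c) + a (constant in c for c>0);
    kept only for comparison behind the ``literal_form`` flag."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(c > 0, vmax / km + a, a)


def dark_ratio(spectrum: Spectrum, lipid_present: bool) -> float:
    """Dark complex-formation ratio: F648/F635 without lipids, F658/F635 with
    OPT lipids.  The spectrum should be normalized and unilluminated."""
    num_nm, den_nm = DARK_RATIO_NM["OPT" if lipid_present else "none"]
    den = intensity_at(spectrum, den_nm)
    if den <= 0:
        raise RatioError(f"denominator intensity at {den_nm} nm is not positive")
    return intensity_at(spectrum, num_nm) / den


def light_ratio(spectrum: Spectrum) -> float:
    """Product/substrate ratio F Chlide / F Pchlide of an illuminated spectrum.

    Intensities are the windowed peak maxima (674–695 over 632–655 nm).  A
    fully converted sample leaves no measurable substrate signal (only the
    far tail of the product band); the ratio is then flagged as ``inf``
    rather than reported as a meaningless large number.  The guard fires when
    the substrate peak is below 1e-4 of the product peak.
    """
    _, chl = peak_maximum(spectrum, CHLIDE_WINDOW)
    _, pch = peak_maximum(spectrum, PCHLIDE_WINDOW)
    if pch <= 0 or (chl > 0 and pch < 1e-4 * chl):
        return math.inf if chl > 0 else math.nan
    return max(chl, 0.0) / pch


def _heuristic_p0(c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = float(np.min(y))
    vmax0 = float(np.max(y) - np.min(y))
    half = a0 + 0.5 * vmax0
    above = c[y >= half]
    km0 = float(above.min()) if above.size and above.min() > 0 else float(np.median(c[c > 0]))
    return max(vmax0, 1e-12), max(km0, 1e-9), a0


def fit_modified_mm(
    series: TitrationSeries,
    init: tuple[float, float, float] | None = None,
    literal_form: bool = False,
) -> MMFit:
    """Unweighted least-squares fit of the modified Michaelis–Menten curve.

    Requires at least four distinct concentrations (three parameters plus one
    degree of freedom).  The default start is data-driven (a = min y, vmax =
    range, KM = concentration at half range) with a 7-point log-spaced KM
    multi-start fallback; the best residual sum of squares wins.  Standard
    errors come from the Jacobian-based covariance of the fit.  A fit that
    fails, lands on a non-positive KM, or leaves KM unresolved (standard error
    an order of magnitude above the estimate) is flagged unconverged — never
    silently returned as a valid constant.
    """
    c, y = series.concentrations, series.values
    if np.unique(c).size < 4:
        raise ValueError("fit requires at least 4 distinct concentrations")
    model = mm_curve_literal if literal_form else mm_curve

    cpos = c[c > 0]
    km_grid = np.geomspace(cpos.min() / 4.0, cpos.max() * 4.0, 7)
    starts = [init or _heuristic_p0(c, y)]
    starts += [(starts[0][0], km, starts[0][2]) for km in km_grid]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                model, c, y, p0=p0,
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000, xtol=1e-13, ftol=1e-13,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(c, *popt) - y) ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, popt, pcov)
    if best is None:
        nan = float("nan")
        return MMFit(nan, nan, nan, nan, nan, nan, False, math.inf, c.size)

    rss, popt, pcov = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.inf)
    vmax, km, a = (float(v) for v in popt)
    converged = bool(
        km > 0
        and np.all(np.isfinite(se))
        and se[1] < 10.0 * km
        and abs(vmax) > 1e-9
    )
    return MMFit(vmax, km, a, float(se[0]), float(se[1]), float(se[2]),
                 converged, rss, c.size)


# ---------------------------------------------------------------------------
# dataset-level K_M table

def build_series(samples, kind: str, isoform: str, lipid: str) -> TitrationSeries:
    """Assemble one titration series from generated/loaded samples.

    Replicate spectra of a condition are normalized then averaged before the
    ratio is computed, so each concentration contributes one point.
    """
    groups: dict[float, list[Spectrum]] = {}
    for s in samples:
        meta = s.meta
        if meta.get("isoform") != isoform or meta.get("lipid") != lipid:
            continue
        spec = s.illuminated if kind == "light_ratio" else s.dark
        groups.setdefault(float(meta["dinucleotide_uM"]), []).append(spec)
    if not groups:
        raise ValueError(f"no samples for isoform={isoform!r}, lipid={lipid!r}")
    concs, values = [], []
    for conc in sorted(groups):
        mean, _sd = average_replicates(groups[conc])
        if kind == "light_ratio":
            val = light_ratio(mean)
        else:
            val = dark_ratio(normalize(mean), lipid_present=(lipid == "OPT"))
        if math.isfinite(val):
            concs.append(conc)
            values.append(val)
    return TitrationSeries(np.array(concs), np.array(values), kind, isoform, lipid)


def km_table(samples) -> pd.DataFrame:
    """Fit K_M^D and K_M^L for every (isoform, lipid) group of a dataset.

    Input samples must provide paired dark and illuminated spectra across a
    concentration series (a :class:`~porlab.simulate_spectra.TitrationSample`
    list or equivalent objects with ``dark``/``illuminated``/``meta``).
    Returns one row per group with estimates, standard errors, log10 pairs for
    plotting, convergence flags, and whether the group shows the K_M^L < K_M^D
    ordering seen for every measured isoform.
    """
    for s in samples:
        if s.illuminated is None:
            raise ValueError(
                f"sample {s.meta.get('sample_id')} lacks an illuminated partner"
            )
    groups = sorted({(s.meta["isoform"], s.meta["lipid"]) for s in samples})
    rows = []
    for isoform, lipid in groups:
        dark_fit = fit_modified_mm(build_series(samples, "dark_ratio", isoform, lipid))
        light_fit = fit_modified_mm(build_series(samples, "light_ratio", isoform, lipid))
        rows.append({
            "isoform": isoform,
            "lipid": lipid,
            "KM_D": dark_fit.km, "KM_D_se": dark_fit.km_se,
            "KM_L": light_fit.km, "KM_L_se": light_fit.km_se,
            "vmax_D": dark_fit.vmax, "a_D": dark_fit.a,
            "vmax_L": light_fit.vmax, "a_L": light_fit.a,
            "converged_D": dark_fit.converged, "converged_L": light_fit.converged,
            "log10_KM_D": math.log10(dark_fit.km) if dark_fit.km > 0 else math.nan,
            "log10_KM_L": math.log10(light_fit.km) if light_fit.km > 0 else math.nan,
            "km_l_below_km_d": bool(light_fit.km < dark_fit.km),
        })
    return pd.DataFrame(rows)
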