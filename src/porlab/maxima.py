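"""Oligomerization index, lipid optimum, and emission-maximum pairing.

The oligomerization index is the base-10 logarithm of the normalized
intensity at 658 nm (NADPH samples) or 647 nm (NADP+ samples) over that at
631 nm: oligomeric membrane-bound complexes emit red-shifted, free pigment
near 631 nm, so the index rises as oligomers form.  Plotting it against lipid
concentration exposes an optimal lipid level for most isoforms (concave-down
profile) and a monotone rise for the rest.

The pairing analysis matches each sample's substrate emission maximum
(632–655 nm window, dark spectrum) with its product maximum (674–695 nm,
after 20 s illumination), keeping samples with at least 1 μM NADPH, where the
product maximum is reliably measurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    CHLIDE_WINDOW,
    PCHLIDE_WINDOW,
    Spectrum,
    intensity_at,
    normalize,
    peak_maximum,
)

#: index wavelengths (numerator nm by dinucleotide, shared denominator nm)
OLIGO_NUMERATOR_NM = {"NADPH": 658.0, "NADP+": 647.0}
OLIGO_DENOMINATOR_NM = 631.0

Shape = Literal["concave_down", "monotone_increasing", "flat"]


class IndexError_(ValueError):
    """Raised when an index is undefined (non-positive intensity)."""


def oligo_index(
    spectrum: Spectrum,
    dinucleotide: str = "NADPH",
    numerator_nm: float | None = None,
    denominator_nm: float = OLIGO_DENOMINATOR_NM,
) -> float:
    """log10 of the oligomer/free-pigment intensity ratio of a dark spectrum.

    Defaults: log10(F658/F631) for NADPH, log10(F647/F631) for NADP+.  Both
    wavelengths are configurable (some analyses quote a ~635 nm denominator).
    Scale-invariant: uses intensities at two wavelengths of one spectrum only.
    """
    if numerator_nm is None:
        if dinucleotide not in OLIGO_NUMERATOR_NM:
            raise ValueError(f"no default index wavelength for dinucleotide {dinucleotide!r}")
        numerator_nm = OLIGO_NUMERATOR_NM[dinucleotide]
    num = intensity_at(spectrum, numerator_nm)
    den = intensity_at(spectrum, denominator_nm)
    if num <= 0 or den <= 0:
        raise IndexError_(
            f"non-positive intensity at {numerator_nm} or {denominator_nm} nm"
        )
    return math.log10(num / den)


@dataclass(frozen=True)
class OligoIndexSeries:
    """Oligomerization index versus lipid concentration."""

    lipid_concs: np.ndarray
    index: np.ndarray
    dinucleotide: str = "NADPH"

    def __post_init__(self) -> None:
        c = np.asarray(self.lipid_concs, dtype=float)
        v = np.asarray(self.index, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise ValueError("lipid_concs and index must be equal-length 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("index values must be finite")
        object.__setattr__(self, "lipid_concs", c)
        object.__setattr__(self, "index", v)


def lipid_optimum(series: OligoIndexSeries, noise_sd: float = 0.0) -> tuple[float, Shape]:
    """Optimal lipid concentration and profile shape of an index series.

    The optimum is the tested concentration maximizing the index (ties break
    to the lowest concentration).  The series is classified
    ``monotone_increasing`` when the maximum sits at the largest tested
    concentration and no interior point exceeds the final point by more than
    2×``noise_sd``; an all-equal series (within tolerance) is ``flat`` with
    the optimum at the lowest concentration; anything else is
    ``concave_down``.
    """
    c, v = series.lipid_concs, series.index
    if np.unique(c).size < 4:
        raise ValueError("lipid_optimum requires at least 4 lipid concentrations")
    order = np.argsort(c, kind="stable")
    c, v = c[order], v[order]
    tol = 2.0 * noise_sd
    if np.max(v) - np.min(v) <= tol:
        return float(c[0]), "flat"
    i_max = int(np.argmax(v))  # first occurrence -> lowest conc on ties
    if v[-1] >= np.max(v[:-1]) - tol:
        return float(c[-1]), "monotone_increasing"
    return float(c[i_max]), "concave_down"


def index_series(spectra: Sequence[Spectrum], dinucleotide: str = "NADPH") -> OligoIndexSeries:
    """Build an index-vs-lipid series from dark spectra (replicates averaged)."""
    groups: dict[float, list[float]] = {}
    for s in spectra:
        idx = oligo_index(normalize(s), dinucleotide)
        groups.setdefault(float(s.meta["lipid_uM"]), []).append(idx)
    concs = np.array(sorted(groups))
    vals = np.array([np.mean(groups[c]) for c in concs])
    return OligoIndexSeries(concs, vals, dinucleotide)


# ---------------------------------------------------------------------------
# emission-maximum pairing

@dataclass(frozen=True)
class MaximaPair:
    """Substrate/product emission-maximum pair of one sample."""

    pchlide_max: float
    chlide_max: float
    meta: dict = field(default_factory=dict, compare=False)


def pair_maxima(samples, min_nadph: float = 1.0) -> tuple[list[MaximaPair], dict]:
    """Pair dark (substrate) and illuminated (product) emission maxima.

    Keeps samples with NADPH concentration of at least ``min_nadph`` μM
    (inclusive threshold); NADP+ samples never enter (no product forms); a
    dark spectrum without an illuminated partner is skipped with a warning.
    Returns the pairs and a counts report whose exclusion categories sum to
    the input count.
    """
    pairs: list[MaximaPair] = []
    report = {"n_input": 0, "n_retained": 0, "n_below_threshold": 0,
              "n_wrong_dinucleotide": 0, "n_orphan": 0}
    for s in samples:
        report["n_input"] += 1
        meta = s.meta
        if meta.get("dinucleotide") != "NADPH":
            report["n_wrong_dinucleotide"] += 1
            continue
        if float(meta.get("dinucleotide_uM", 0.0)) < min_nadph:
            report["n_below_threshold"] += 1
            continue
        if s.illuminated is None:
            warnings.warn(
                f"sample {meta.get('sample_id')} has no illuminated partner; skipped",
                stacklevel=2,
            )
            report["n_orphan"] += 1
            continue
        pch_nm, _ = peak_maximum(normalize(s.dark), PCHLIDE_WINDOW)
        chl_nm, _ = peak_maximum(normalize(s.illuminated), CHLIDE_WINDOW)
        pairs.append(MaximaPair(pch_nm, chl_nm, meta=dict(meta)))
        report["n_retained"] += 1
    return pairs, report


def pairs_frame(pairs: Sequence[MaximaPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.meta.get("sample_id"),
                "isoform": p.meta.get("isoform"),
                "lipid": p.meta.get("lipid"),
                "nadph_uM": p.meta.get("dinucleotide_uM"),
                "pchlide_max_nm": p.pchlide_max,
                "chlide_max_nm": p.chlide_max,
            }
            for p in pairs
        ]
    )


def _histogram(values: np.ndarray, lo: float, hi: float, bin_width: float):
    edges = np.arange(math.floor(lo), math.ceil(hi) + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def maxima_histograms(pairs: Sequence[MaximaPair], bin_width: float = 1.0) -> dict:
    """Distributions of substrate and product maxima, overall and per isoform.

    Bins are aligned to integer nm edges (maxima live on the 0.5 nm grid).
    Each axis also carries a per-isoform split and a lipid-containing split.
    Bin counts always sum to the number of pairs.
    """
    if not pairs:
        raise ValueError("maxima_histograms requires at least one pair")
    out: dict = {"bin_width": bin_width}
    for axis, window in (("pchlide", PCHLIDE_WINDOW), ("chlide", CHLIDE_WINDOW)):
        values = np.array([getattr(p, f"{axis}_max") for p in pairs])
        counts, edges = _histogram(values, window[0], window[1], bin_width)
        per_isoform = {}
        for iso in sorted({p.meta.get("isoform") for p in pairs}):
            vals_i = np.array(
                [getattr(p, f"{axis}_max") for p in pairs if p.meta.get("isoform") == iso]
            )
            per_isoform[iso], _ = _histogram(vals_i, window[0], window[1], bin_width)
        lipid_vals = np.array(
            [getattr(p, f"{axis}_max") for p in pairs if p.meta.get("lipid") not in (None, "none")]
        )
        with_lipid, _ = _histogram(lipid_vals, window[0], window[1], bin_width)
        out[axis] = {
            "edges": edges,
            "counts": counts,
            "per_isoform": per_isoform,
            "with_lipid": with_lipid,
        }
    return out


@dataclass(frozen=True)
class ConditionalResult:
    """Product-maximum distribution conditioned on a substrate-maximum window."""

    center: float
    halfwidth: float
    chlide_maxima: np.ndarray
    mode: float | None  # most frequent product maximum; None if empty

    @property
    def n(self) -> int:
        return int(self.chlide_maxima.size)


def conditional_chlide(
    pairs: Sequence[MaximaPair], center: float, halfwidth: float = 2.5
) -> ConditionalResult:
    """Product maxima of pairs whose substrate maximum lies within
    ``center ± halfwidth`` nm.  An empty subset returns an explicit empty
    result (mode ``None``) rather than raising."""
    if not pairs:
        raise ValueError("conditional_chlide requires a non-empty pair list")
    sel = np.array(
        [p.chlide_max for p in pairs if abs(p.pchlide_max - center) <= halfwidth + 1e-9]
    )
    if sel.size == 0:
        return ConditionalResult(center, halfwidth, sel, None)
    vals, counts = np.unique(sel, return_counts=True)
    mode = float(vals[np.argmax(counts)])  # ties -> lowest wavelength
    return ConditionalResult(center, halfwidth, sel, mode)
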