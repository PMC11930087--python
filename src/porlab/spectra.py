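"""Reading, writing and preprocessing of 77 K fluorescence emission spectra.

A spectrum is a two-column table (wavelength in nm, fluorescence intensity in
arbitrary units) on a uniform grid, by default 600–790 nm in 0.5 nm steps as
recorded by the spectrofluorometer.  All downstream ratio and peak analyses
assume spectra have been normalized to their maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GRID_START = 600.0
GRID_STOP = 790.0
GRID_STEP = 0.5

#: windows used to locate the substrate and product emission maxima (nm)
PCHLIDE_WINDOW = (632.0, 655.0)
CHLIDE_WINDOW = (674.0, 695.0)


def default_grid() -> np.ndarray:
    """The instrument wavelength grid: 600–790 nm, 0.5 nm step (381 points)."""
    n = int(round((GRID_STOP - GRID_START) / GRID_STEP)) + 1
    return GRID_START + GRID_STEP * np.arange(n)


class SpectrumError(ValueError):
    """Raised for malformed spectral data or invalid spectral operations."""


@dataclass(frozen=True)
class PeakWindow:
    """A wavelength window [lo, hi] (nm) within the recorded range."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (GRID_START <= self.lo < self.hi <= GRID_STOP):
            raise SpectrumError(
                f"invalid peak window [{self.lo}, {self.hi}]: must satisfy "
                f"{GRID_START} <= lo < hi <= {GRID_STOP}"
            )


@dataclass(frozen=True)
class Spectrum:
    """An emission spectrum on a uniform, strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumError(
                f"wavelengths and intensities must be 1-D and equal length "
                f"(got {wl.shape} vs {it.shape})"
            )
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two grid points")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise SpectrumError("wavelength grid must be uniform")
        if not np.all(np.isfinite(it)):
            raise SpectrumError("intensities must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def with_meta(self, **kwargs) -> "Spectrum":
        return replace(self, meta={**self.meta, **kwargs})


def read_spectrum(path, meta: dict | None = None) -> Spectrum:
    """Read a two-column wavelength/intensity table (TSV or CSV, header optional).

    Raises :class:`SpectrumError` naming the offending line for ragged rows,
    non-numeric cells or a non-monotone grid.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if lineno == 1 and any(_not_numeric(p) for p in parts):
                continue  # header row
            if len(parts) != 2:
                raise SpectrumError(
                    f"{path}:{lineno}: expected 2 columns, found {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc
    if len(rows) < 2:
        raise SpectrumError(f"{path}: fewer than two data rows")
    wl, it = map(np.asarray, zip(*rows))
    if np.any(np.diff(wl) <= 0):
        bad = int(np.argmax(np.diff(wl) <= 0)) + 2
        raise SpectrumError(f"{path}: wavelengths not strictly increasing at data row {bad}")
    return Spectrum(wl, it, meta=dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as a two-column TSV with a header (round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("wavelength_nm\tintensity\n")
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(wl)!r}\t{float(it)!r}\n")


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the maximum is exactly 1 (all spectra were
    normalized at their maxima before any ratio or maximum analysis)."""
    peak = float(np.max(spectrum.intensities))
    if peak <= 0:
        raise SpectrumError("cannot normalize: maximum intensity is not positive")
    return replace(spectrum, intensities=spectrum.intensities / peak)


def smooth(spectrum: Spectrum, width: int) -> Spectrum:
    """Optional centered moving average of odd width, for noisy real spectra."""
    if width % 2 != 1 or width < 1:
        raise SpectrumError("smoothing width must be a positive odd integer")
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(spectrum.intensities, pad, mode="edge")
    return replace(spectrum, intensities=np.convolve(padded, kernel, mode="valid"))


def _window_slice(spectrum: Spectrum, window) -> slice:
    lo, hi = (window.lo, window.hi) if isinstance(window, PeakWindow) else window
    wl = spectrum.wavelengths
    mask = (wl >= lo - 1e-9) & (wl <= hi + 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SpectrumError(f"window [{lo}, {hi}] does not overlap the grid")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def peak_maximum(spectrum: Spectrum, window, refine: bool = False) -> tuple[float, float]:
    """Locate the emission maximum within a window.

    Returns ``(wavelength_nm, intensity)`` at the grid argmax; ties resolve to
    the lowest wavelength.  With ``refine=True`` a three-point parabolic
    sub-grid estimate of the position is returned instead (intensity stays the
    grid value); refinement is off by default so maxima are reported at the
    0.5 nm collection resolution.
    """
    sl = _window_slice(spectrum, window)
    wl = spectrum.wavelengths[sl]
    it = spectrum.intensities[sl]
    i = int(np.argmax(it))  # first occurrence = lowest wavelength on ties
    peak_wl, peak_it = float(wl[i]), float(it[i])
    if refine and 0 < i < it.size - 1:
        y0, y1, y2 = it[i - 1], it[i], it[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # genuine interior maximum
            peak_wl += 0.5 * (y0 - y2) / denom * spectrum.step
    return peak_wl, peak_it


def intensity_at(spectrum: Spectrum, wavelength: float) -> float:
    """Intensity at the grid point nearest to ``wavelength`` (exact on-grid)."""
    wl = spectrum.wavelengths
    if wavelength < wl[0] - 1e-9 or wavelength > wl[-1] + 1e-9:
        raise SpectrumError(
            f"wavelength {wavelength} nm outside grid range [{wl[0]}, {wl[-1]}]"
        )
    return float(spectrum.intensities[int(np.argmin(np.abs(wl - wavelength)))])


def average_replicates(spectra: Sequence[Spectrum]) -> tuple[Spectrum, np.ndarray]:
    """Average replicate spectra after normalization; returns (mean, SD).

    Replicates of one condition are normalized individually, then averaged
    point-wise; the per-point standard deviation between replicates is
    retained (the shaded-band uncertainty in the figures).
    """
    if not spectra:
        raise SpectrumError("no spectra to average")
    grids = [s.wavelengths for s in spectra]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise SpectrumError("replicate spectra must share one wavelength grid")
    stack = np.vstack([normalize(s).intensities for s in spectra])
    mean = Spectrum(grids[0], stack.mean(axis=0), meta=dict(spectra[0].meta))
    return mean, stack.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# manifest handling

MANIFEST_COLUMNS = [
    "sample_id", "file", "isoform", "pigment", "dinucleotide", "dinucleotide_uM",
    "lipid", "lipid_uM", "illuminated", "replicate", "seed",
]


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest TSV; validates the required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumError(f"manifest {path} lacks required columns: {missing}")
    return df


def load_dataset(manifest_path) -> list[Spectrum]:
    """Load every spectrum referenced by a manifest, attaching its metadata row.

    A manifest row whose file is missing raises an error naming the sample_id.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    out = []
    for _, row in df.iterrows():
        fpath = base / str(row["file"])
        if not fpath.exists():
            raise SpectrumError(
                f"sample {row['sample_id']}: spectrum file {fpath} not found"
            )
        out.append(read_spectrum(fpath, meta=row.to_dict()))
    return out


def _not_numeric(token: str) -> bool:
    try:
        float(token)
        return False
    except ValueError:
        return True
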