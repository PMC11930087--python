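"""Synthetic 77 K emission-spectrum generator.

Emulates the statistical structure of the low-temperature fluorescence
datasets: composition-dependent Gaussian bands on the instrument grid,
NADPH binding isotherms in the dark, 20 s photoconversion of the complexed
substrate, lipid-titration oligomerization profiles, and replicate noise.
Ground-truth parameters travel with every sample so the downstream ratio,
fitting and pairing stages can be tested against known answers.

The emission-center lookup encodes the observed phenomenology of the real
complexes (e.g. ternary Pchlide complexes at ~648 nm without lipids, ~655 nm
on MGDG-rich membranes, product complexes at 681–687 nm); centers the
measurements do not pin down (free pigment in buffer at 77 K, the NADP+
no-lipid complex) are documented stand-ins and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, default_grid, write_spectrum

Pigment = Literal["Pchlide", "Chlide"]
Dinucleotide = Literal["none", "NADP+", "NADPH"]

#: 2-fold serial dilution ladder spanning the measured range, 62.5 nM to 200 uM
DEFAULT_NADPH_LADDER_UM: tuple[float, ...] = tuple(0.0625 * 2.0**k for k in range(12)) + (200.0,)

#: default Gaussian sigma of a 77 K emission band (nm); narrow 77 K peaks
DEFAULT_BAND_SIGMA = 6.0

#: stand-in centers for pigment free in buffer (not stated by measurements)
FREE_PCHLIDE_NM = 632.0
FREE_CHLIDE_NM = 676.0


class CompositionError(ValueError):
    """Raised when a sample composition has no known emission center."""


@dataclass(frozen=True)
class SpectralBand:
    """One Gaussian emission band: center (nm), sigma (nm), amplitude (a.u.)."""

    center: float
    width: float = DEFAULT_BAND_SIGMA
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")
        if not (600.0 <= self.center <= 790.0):
            raise ValueError("band center must lie within 600-790 nm")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((grid - self.center) ** 2) / (2 * self.width**2))


@dataclass(frozen=True)
class Composition:
    """Reaction-mixture composition of one sample."""

    pigment: Pigment
    dinucleotide: Dinucleotide = "none"
    dinucleotide_uM: float = 0.0
    lipid: str = "none"
    lipid_uM: float = 0.0
    isoform: str = "AtPORB"

    def __post_init__(self) -> None:
        if self.dinucleotide_uM < 0 or self.lipid_uM < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.lipid == "none" and self.lipid_uM != 0:
            raise ValueError("lipid='none' requires lipid_uM=0")


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of one synthetic titration.

    km_d is the NADPH half-saturation of dark complex formation (μM); km_l the
    half-saturation of the 20 s photoconversion yield (μM); vmax_d/vmax_l the
    amplitude scales of the complex band and of the convertible pigment pool;
    a_d/a_l flat baseline offsets; conv_max the maximal converted fraction of
    the convertible pool; noise_sigma the replicate noise as a fraction of the
    peak intensity.
    """

    km_d: float = 50.0
    km_l: float = 5.0
    vmax_d: float = 1.0
    vmax_l: float = 0.3
    a_d: float = 0.0
    a_l: float = 0.0
    conv_max: float = 0.95
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.km_d <= 0 or self.km_l <= 0:
            raise ValueError("km_d and km_l must be positive")
        if not (0.0 <= self.conv_max <= 1.0):
            raise ValueError("conv_max must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


#: default emission maxima (nm) by (pigment, dinucleotide, lipid).
#: Measured complexes: ternary Pchlide:NADPH complexes at ~648 nm lipid-free
#: and with PG, ~655 nm on OPT membranes, ~652 nm on low-MGDG membranes;
#: Pchlide:NADP+ at ~638 nm with PG and ~647 nm with OPT; Chlide complexes at
#: ~687 (NADPH) and ~684 nm (NADP+) lipid-free.  641 nm (Pchlide:NADP+,
#: lipid-free: middle of the observed 8-nm spread) and the lipid-supplemented
#: Chlide centers are stand-ins.
EMISSION_CENTERS_NM: dict[tuple[str, str, str], float] = {
    ("Pchlide", "NADPH", "none"): 648.0,
    ("Pchlide", "NADPH", "PG"): 648.0,
    ("Pchlide", "NADPH", "OPT"): 655.0,
    ("Pchlide", "NADPH", "lowMGDG"): 652.0,
    ("Pchlide", "NADP+", "none"): 641.0,
    ("Pchlide", "NADP+", "PG"): 638.0,
    ("Pchlide", "NADP+", "OPT"): 647.0,
    ("Chlide", "NADPH", "none"): 687.0,
    ("Chlide", "NADP+", "none"): 684.0,
    ("Chlide", "NADPH", "PG"): 689.0,
    ("Chlide", "NADPH", "OPT"): 690.0,
    ("Chlide", "NADP+", "PG"): 686.0,
    ("Chlide", "NADP+", "OPT"): 687.0,
}

#: dark-complex emission maximum -> product-complex emission maximum (nm).
#: Substrate complexes at 637/648/655 nm typically yield product complexes
#: at 681/683/687 nm respectively.
PRODUCT_COUPLING_NM: dict[float, float] = {637.0: 681.0, 648.0: 683.0, 655.0: 687.0}


def emission_center(
    composition: Composition, overrides: dict[tuple[str, str, str], float] | None = None
) -> float:
    """Default emission maximum (nm) for a composition.

    Free pigment (no dinucleotide) maps to the free-pigment stand-in center;
    an unknown (pigment, dinucleotide, lipid) combination without an override
    raises :class:`CompositionError`.
    """
    if composition.dinucleotide == "none" or composition.dinucleotide_uM == 0:
        return FREE_PCHLIDE_NM if composition.pigment == "Pchlide" else FREE_CHLIDE_NM
    key = (composition.pigment, composition.dinucleotide, composition.lipid)
    table = {**EMISSION_CENTERS_NM, **(overrides or {})}
    if key not in table:
        raise CompositionError(
            f"no default emission center for {key}; supply an override"
        )
    return table[key]


def product_center(pchlide_center: float) -> float:
    """Product (Chlide) complex center coupled to a substrate complex center.

    Exact known couplings are used when the center matches one of the three
    canonical substrate classes; otherwise the mean red-shift (+34 nm) of the
    known couplings is applied.
    """
    if pchlide_center in PRODUCT_COUPLING_NM:
        return PRODUCT_COUPLING_NM[pchlide_center]
    shifts = [v - k for k, v in PRODUCT_COUPLING_NM.items()]
    return pchlide_center + float(np.mean(shifts))


def render_spectrum(
    bands: Sequence[SpectralBand],
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline: float = 0.0,
    meta: dict | None = None,
) -> Spectrum:
    """Sum Gaussian bands on the instrument grid and add replicate noise.

    Noise is i.i.d. Gaussian with SD ``noise_sigma * max(intensity)``;
    deterministic given the seed.  An empty band list is an error.
    """
    if len(bands) == 0:
        raise ValueError("render_spectrum requires at least one band")
    grid = default_grid()
    intensities = np.full_like(grid, float(baseline))
    for band in bands:
        intensities = intensities + band.profile(grid)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        scale = noise_sigma * float(np.max(intensities))
        if scale > 0:
            intensities = intensities + rng.normal(0.0, scale, size=grid.size)
    return Spectrum(grid, intensities, meta=dict(meta or {}))


def bound_fraction(conc: float, km: float) -> float:
    """Equilibrium bound fraction c/(km + c) of the dark binding isotherm."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    return conc / (km + conc) if conc > 0 else 0.0


@dataclass(frozen=True)
class TitrationSample:
    """One titration condition: dark and illuminated spectra plus metadata.

    ``illuminated`` may be ``None`` for an orphan dark measurement."""

    dark: Spectrum
    illuminated: Spectrum | None
    meta: dict


def samples_from_spectra(spectra) -> "list[TitrationSample]":
    """Group loaded spectra into dark/illuminated sample pairs by sample_id.

    The inverse of :func:`write_dataset` + :func:`~porlab.spectra.load_dataset`:
    each manifest sample_id contributes one :class:`TitrationSample`; a sample
    with only a dark spectrum gets ``illuminated=None``.
    """
    by_id: dict[str, dict[int, Spectrum]] = {}
    order: list[str] = []
    for spec in spectra:
        sid = str(spec.meta["sample_id"])
        if sid not in by_id:
            by_id[sid] = {}
            order.append(sid)
        by_id[sid][int(spec.meta.get("illuminated", 0))] = spec
    out = []
    for sid in order:
        group = by_id[sid]
        if 0 not in group:
            raise ValueError(f"sample {sid} has no dark spectrum")
        meta = {k: v for k, v in group[0].meta.items() if k not in ("file", "illuminated")}
        out.append(TitrationSample(group[0], group.get(1), meta))
    return out


def dark_bands(
    params: GeneratorParams, conc: float, composition: Composition
) -> list[SpectralBand]:
    """Bands of the unilluminated sample: constant free-pigment band plus a
    complex band whose amplitude follows the binding isotherm."""
    f = bound_fraction(conc, params.km_d)
    comp = replace(composition, dinucleotide_uM=conc)
    center = emission_center(comp) if conc > 0 else None
    bands = [SpectralBand(FREE_PCHLIDE_NM, amplitude=1.0)]
    if center is not None and params.vmax_d * f > 0:
        bands.append(SpectralBand(center, amplitude=params.vmax_d * f))
    return bands


def illuminated_bands(
    params: GeneratorParams, conc: float, composition: Composition
) -> list[SpectralBand]:
    """Bands after 20 s illumination.

    Only the convertible pigment pool (amplitude ``vmax_l``, the enzyme-bound
    pigment that can turn over during illumination) photoconverts; free
    pigment in the frozen matrix does not.  The converted amplitude
    ``conv_max * vmax_l * c/(km_l + c)`` appears as the product band at the
    coupled product center and is debited proportionally from the substrate
    bands, so total band amplitude is conserved exactly.
    """
    pch = dark_bands(params, conc, composition)
    total = sum(b.amplitude for b in pch)
    converted = params.conv_max * params.vmax_l * bound_fraction(conc, params.km_l)
    converted = min(converted, total)  # cannot convert more than is present
    if converted <= 0:
        return list(pch)
    scale = (total - converted) / total
    out = [replace(b, amplitude=b.amplitude * scale) for b in pch]
    comp = replace(composition, dinucleotide_uM=conc)
    chl_center = product_center(emission_center(comp))
    out.append(SpectralBand(chl_center, amplitude=converted))
    return out


def simulate_titration(
    params: GeneratorParams,
    concs: Sequence[float],
    composition: Composition,
    replicates: int = 2,
) -> list[TitrationSample]:
    """Simulate a full dark + illuminated dinucleotide titration.

    Replicates of a condition differ only by their noise stream.  Metadata of
    every sample carries the ground-truth generator parameters.
    """
    concs = list(concs)
    if not concs:
        raise ValueError("concs must be non-empty")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be nonnegative")
    children = np.random.SeedSequence(params.seed).spawn(len(concs) * replicates * 2)
    seeds = iter(children)
    samples = []
    for i, conc in enumerate(concs):
        for rep in range(replicates):
            meta = {
                "sample_id": f"{composition.isoform}_{composition.lipid}_c{i:02d}_r{rep}",
                "isoform": composition.isoform,
                "pigment": composition.pigment,
                "dinucleotide": composition.dinucleotide,
                "dinucleotide_uM": conc,
                "lipid": composition.lipid,
                "lipid_uM": composition.lipid_uM,
                "replicate": rep,
                "seed": params.seed,
                "true_km_d": params.km_d,
                "true_km_l": params.km_l,
                "true_conv_max": params.conv_max,
            }
            dark = render_spectrum(
                dark_bands(params, conc, composition),
                params.noise_sigma,
                np.random.default_rng(next(seeds)),
                baseline=params.a_d,
                meta={**meta, "illuminated": 0},
            )
            lit = render_spectrum(
                illuminated_bands(params, conc, composition),
                params.noise_sigma,
                np.random.default_rng(next(seeds)),
                baseline=params.a_l,
                meta={**meta, "illuminated": 1},
            )
            samples.append(TitrationSample(dark, lit, meta))
    return samples


# ---------------------------------------------------------------------------
# lipid titration

#: log10-width of the unimodal oligomer-band profile (decades)
LIPID_PROFILE_WIDTH = 0.5


def lipid_band_amplitudes(
    lipid_uM: float, optimum_uM: float, monotone: bool = False
) -> tuple[float, float]:
    """(oligomer band, free-pigment band) amplitudes at one lipid concentration.

    The oligomer band peaks at the optimal lipid concentration and decays on a
    log scale on either side (membrane dilution of subunits at high lipid);
    the free-pigment band starts to grow once the optimum is passed.  The
    monotone variant (weak inter-subunit interactions never limited by
    dilution within the tested range) saturates instead of turning down.
    """
    if optimum_uM <= 0 or lipid_uM <= 0:
        raise ValueError("lipid and optimum concentrations must be positive")
    x = np.log10(lipid_uM / optimum_uM)
    if monotone:
        oligo = lipid_uM / (lipid_uM + optimum_uM)
        free = 0.12
    else:
        oligo = float(np.exp(-(x**2) / (2 * LIPID_PROFILE_WIDTH**2)))
        free = 0.12 * (1.0 + 2.0 * max(0.0, x) ** 2)
    return oligo, free


def simulate_lipid_titration(
    lipid_concs: Sequence[float],
    optimum_uM: float,
    params: GeneratorParams,
    composition: Composition | None = None,
    monotone: bool = False,
    replicates: int = 2,
) -> list[Spectrum]:
    """Simulate dark spectra of an OPT-lipid titration at fixed dinucleotide.

    Every spectrum's metadata records the planted optimum and whether the
    profile was monotone, so the oligomerization-index analysis can be checked
    against ground truth.
    """
    if optimum_uM <= 0:
        raise ValueError("optimum must be positive")
    composition = composition or Composition(
        "Pchlide", "NADPH", 200.0, lipid="OPT", lipid_uM=0.0
    )
    oligo_center = emission_center(replace(composition, lipid="OPT", lipid_uM=100.0))
    children = iter(np.random.SeedSequence(params.seed).spawn(len(lipid_concs) * replicates))
    out = []
    for i, lc in enumerate(lipid_concs):
        oligo, free = lipid_band_amplitudes(lc, optimum_uM, monotone=monotone)
        bands = [
            SpectralBand(oligo_center, amplitude=oligo),
            SpectralBand(FREE_PCHLIDE_NM, amplitude=free),
        ]
        for rep in range(replicates):
            meta = {
                "sample_id": f"{composition.isoform}_lip{i:02d}_r{rep}",
                "isoform": composition.isoform,
                "pigment": composition.pigment,
                "dinucleotide": composition.dinucleotide,
                "dinucleotide_uM": composition.dinucleotide_uM,
                "lipid": "OPT",
                "lipid_uM": lc,
                "illuminated": 0,
                "replicate": rep,
                "seed": params.seed,
                "true_optimum_uM": optimum_uM,
                "true_monotone": int(monotone),
            }
            out.append(
                render_spectrum(
                    bands, params.noise_sigma, np.random.default_rng(next(children)),
                    meta=meta,
                )
            )
    return out


# ---------------------------------------------------------------------------
# emission-maximum pairing dataset

#: canonical substrate-complex classes and the compositions that produce them
MAXIMA_CLASSES = (
    {"center": 637.0, "lipid": "none"},
    {"center": 648.0, "lipid": "none"},
    {"center": 655.0, "lipid": "OPT"},
)


def simulate_maxima_dataset(
    nadph_uM: Sequence[float],
    seed: int = 0,
    class_weights: Sequence[float] = (0.25, 0.4, 0.35),
    jitter_nm: float = 0.5,
    noise_sigma: float = 0.005,
    isoforms: Sequence[str] = ("PinPOR", "AtPORB", "HaPOR3"),
) -> list[TitrationSample]:
    """Simulate dark/illuminated sample pairs for the maxima-pairing analysis.

    Each sample draws one of the three substrate spectral classes (637, 648,
    655 nm); its illuminated spectrum carries the coupled product band (681,
    683, 687 nm).  Both centers receive uniform jitter of at most
    ``jitter_nm``.  Ground truth (class, exact centers) rides in the metadata.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(class_weights, dtype=float)
    weights = weights / weights.sum()
    samples = []
    for i, conc in enumerate(nadph_uM):
        cls = MAXIMA_CLASSES[rng.choice(len(MAXIMA_CLASSES), p=weights)]
        pch_center = cls["center"] + rng.uniform(-jitter_nm, jitter_nm)
        chl_center = product_center(cls["center"]) + rng.uniform(-jitter_nm, jitter_nm)
        meta = {
            "sample_id": f"M{i:04d}",
            "isoform": isoforms[int(rng.integers(len(isoforms)))],
            "pigment": "Pchlide",
            "dinucleotide": "NADPH",
            "dinucleotide_uM": float(conc),
            "lipid": cls["lipid"],
            "lipid_uM": 100.0 if cls["lipid"] != "none" else 0.0,
            "replicate": 0,
            "seed": seed,
            "true_class_nm": cls["center"],
        }
        dark = render_spectrum(
            [SpectralBand(pch_center, amplitude=1.0)],
            noise_sigma, rng, meta={**meta, "illuminated": 0},
        )
        lit = render_spectrum(
            [
                SpectralBand(pch_center, amplitude=0.5),
                SpectralBand(chl_center, amplitude=0.6),
            ],
            noise_sigma, rng, meta={**meta, "illuminated": 1},
        )
        samples.append(TitrationSample(dark, lit, meta))
    return samples


# ---------------------------------------------------------------------------
# dataset export

def write_dataset(samples: Iterable, outdir) -> Path:
    """Write a dataset as one TSV per spectrum plus a manifest TSV.

    Accepts :class:`TitrationSample` items (dark + illuminated) or bare
    :class:`~porlab.spectra.Spectrum` items.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []

    def _emit(spec: Spectrum) -> None:
        meta = dict(spec.meta)
        suffix = "lit" if meta.get("illuminated") else "dark"
        fname = f"{meta['sample_id']}_{suffix}.tsv"
        write_spectrum(spec, outdir / fname)
        meta["file"] = fname
        rows.append(meta)

    for item in samples:
        if isinstance(item, TitrationSample):
            _emit(item.dark)
            _emit(item.illuminated)
        else:
            _emit(item)

    manifest = pd.DataFrame(rows)
    front = [c for c in ("sample_id", "file") if c in manifest.columns]
    manifest = manifest[front + [c for c in manifest.columns if c not in front]]
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
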