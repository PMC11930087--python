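#!/usr/bin/env python
"""Generate the synthetic 77 K spectra datasets used by the spectral track.

Writes three datasets under scratch/datasets/ (bulky regenerable input data;
the downstream drivers read from there): an OPT-lipid NADPH titration
and a lipid-free NADPH titration (dark + illuminated, duplicate replicates,
62.5 nM - 200 uM serial ladder, planted KM_D = 50 uM and KM_L = 5 uM), and
an OPT-lipid titration (2-400 uM) with the oligomer band peaking at 100 uM.
"""

from pathlib import Path

import porlab as pl
from porlab.simulate_spectra import DEFAULT_NADPH_LADDER_UM

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "scratch" / "datasets"

LIPID_CONCS = [2.0, 5.0, 10.0, 20.0, 40.0, 100.0, 200.0, 400.0]


def main() -> None:
    params = pl.GeneratorParams(km_d=50.0, km_l=5.0, noise_sigma=0.01, seed=SEED)
    for lipid in ("OPT", "none"):
        comp = pl.Composition(
            "Pchlide", "NADPH", 0.0, lipid=lipid,
            lipid_uM=400.0 if lipid == "OPT" else 0.0, isoform="HaPOR3",
        )
        samples = pl.simulate_titration(params, DEFAULT_NADPH_LADDER_UM, comp)
        manifest = pl.write_dataset(samples, OUT / f"titration_{lipid}")
        print(f"NADPH titration ({lipid}): {len(samples)} sample pairs -> {manifest}")

    lipid_spectra = pl.simulate_lipid_titration(LIPID_CONCS, 100.0, params)
    manifest = pl.write_dataset(lipid_spectra, OUT / "lipid_titration")
    print(f"lipid titration: {len(lipid_spectra)} dark spectra -> {manifest}")
    print(f"ground truth: KM_D=50 uM, KM_L=5 uM, lipid optimum=100 uM, seed={SEED}")


if __name__ == "__main__":
    main()
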