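#!/usr/bin/env python
"""Ensemble flexibility: RMSF, per-region RMSD and representative selection.

Generates two synthetic conformational ensembles around one reference trace:
(i) a flexibility ensemble with 1 A/axis jitter confined to helix a10
(residues 316-338) to exercise RMSF localization, and (ii) a two-family
ensemble with oligomerization interface II (367-375) rigidly displaced 8 A
in half the members to exercise region-RMSD separation and dynamic (leader)
clustering at the 3 A cutoff.  Writes rmsf.tsv, region_rmsd_summary.tsv and
clusters.tsv under results/, plus the ensembles as multi-model PDBs under
scratch/ensembles/ (bulky, regenerable).
"""

from pathlib import Path

import numpy as np

import porlab as pl
from porlab.simulate_ensemble import EnsembleDesign, make_reference, sample_ensemble

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    reference = make_reference(400, seed=SEED)
    ROOT.mkdir(parents=True, exist_ok=True)
    pdb_dir = Path(__file__).resolve().parent.parent / "scratch" / "ensembles"
    pl.write_models([reference], pdb_dir / "reference.pdb")

    flex_design = EnsembleDesign(n_members=200, jitter_sigma={"helix_a10": 1.0},
                                 seed=SEED + 1)
    flex, _ = sample_ensemble(flex_design, reference)
    table = pl.rmsf(flex)
    table.to_csv(ROOT / "rmsf.tsv", sep="\t", index=False, float_format="%.6g")
    helix = (table.residue >= 316) & (table.residue <= 338)
    print(f"RMSF mean inside helix a10: {table[helix].rmsf_A.mean():.3f} A "
          f"(planted sigma*sqrt(3) = {np.sqrt(3):.3f} A); "
          f"outside: {table[~helix].rmsf_A.mean():.3f} A")

    fam_design = EnsembleDesign(
        n_members=40, jitter_sigma=0.2,
        family_offsets=[{}, {"interface_II": 8.0}], family_fractions=[0.5, 0.5],
        seed=SEED + 2,
    )
    families, truth = sample_ensemble(fam_design, reference)
    pl.write_models(list(families.members), pdb_dir / "two_family_models.pdb")
    truth.to_csv(pdb_dir / "ground_truth.tsv", sep="\t", index=False)

    rmsd_table, summary = pl.region_rmsd(families)
    summary.to_csv(ROOT / "region_rmsd_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print(summary.to_string(index=False))

    clusters = pl.dynamic_cluster(families, cutoff=3.0)
    clusters.assignment.to_csv(ROOT / "clusters.tsv", sep="\t", index=False,
                               float_format="%.6g")
    fam = dict(zip(truth.member, truth.family))
    acc = np.mean([fam[r.member] == fam[r.centroid]
                   for r in clusters.assignment.itertuples()])
    print(f"dynamic clustering at 3 A: {clusters.n_clusters} centroids "
          f"(2 families planted), assignment accuracy {100*acc:.0f}%")


if __name__ == "__main__":
    main()
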