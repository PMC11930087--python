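"""Superposition, RMSF, per-region RMSD and greedy leader clustering.

All metrics share one alignment recipe: each conformation is rigid-body
superposed (optimal least-squares rotation + translation, Kabsch) onto the
reference over all shared Cα; region metrics are then computed in that frame
without any region-local refitting, so a region's RMSD reflects genuine
conformational displacement rather than fitting freedom.

Representative conformations are selected by dynamic (leader) RMSD
clustering: the top-ranked prediction seeds the centroid list; every
subsequent prediction whose region RMSD to all current centroids exceeds the
cutoff (3 Å by default) becomes a new centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import Ensemble, RegionSet, StructureModel, StructureError, DEFAULT_REGIONS


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise StructureError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise StructureError("superposition selection is degenerate (collinear)")


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Sequence[int] | None = None,
) -> tuple[StructureModel, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    The rotation and translation minimize the squared Cα deviation over the
    selection (all residues shared by both models when omitted); the full
    model is transformed and the RMSD over the selection is returned.
    """
    if selection is None:
        selection = np.intersect1d(mobile.residue_ids, reference.residue_ids)
    sel = np.asarray(selection, dtype=int)
    mob_sel = mobile.select(sel)
    ref_sel = reference.select(sel)
    _check_selection(mob_sel)
    _check_selection(ref_sel)
    mob_mean = mob_sel.mean(axis=0)
    ref_mean = ref_sel.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_sel - ref_mean, mob_sel - mob_mean)
    rmsd = float(rssd) / np.sqrt(sel.size)
    moved = rot.apply(mobile.coords - mob_mean) + ref_mean
    return replace(mobile, coords=moved), rmsd


def align_ensemble(ensemble: Ensemble) -> tuple[list[StructureModel], np.ndarray]:
    """Superpose every member onto the reference over all shared Cα."""
    shared = ensemble.shared_residue_ids
    aligned = [superpose(m, ensemble.reference, shared)[0] for m in ensemble.members]
    return aligned, shared


def rmsf(ensemble: Ensemble, about: Literal["mean", "reference"] = "mean") -> pd.DataFrame:
    """Per-residue Cα root-mean-square fluctuation of the ensemble.

    After aligning each member to the reference, RMSF_i is the RMS deviation
    of residue i's Cα across members about the ensemble mean position
    (``about="mean"``, the default) or about the reference coordinates
    (``about="reference"``).  Requires at least two members.
    """
    if len(ensemble.members) < 2:
        raise StructureError("rmsf requires at least 2 ensemble members")
    aligned, shared = align_ensemble(ensemble)
    stack = np.stack([m.select(shared) for m in aligned])  # (M, N, 3)
    center = stack.mean(axis=0) if about == "mean" else ensemble.reference.select(shared)
    fluct = np.sqrt(np.mean(np.sum((stack - center) ** 2, axis=2), axis=0))
    return pd.DataFrame({"residue": shared, "rmsf_A": fluct})


def _rmsd_over(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((coords_a - coords_b) ** 2, axis=1))))


def region_rmsd(
    ensemble: Ensemble, regions: RegionSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-member RMSD of each named region versus the reference.

    Members are globally superposed to the reference over all shared Cα; the
    RMSD over each region's Cα is then measured in that frame without
    refitting.  Returns (per-member table, per-region summary with median and
    first/third quartiles).
    """
    regions = regions or DEFAULT_REGIONS
    aligned, shared = align_ensemble(ensemble)
    shared_set = set(shared.tolist())
    rows = []
    for m in aligned:
        for reg in regions:
            ids = [r for r in reg.residue_ids if r in shared_set]
            if not ids:
                raise StructureError(f"region {reg.name} outside the shared residue span")
            rows.append({
                "member": m.label,
                "region": reg.name,
                "rmsd_A": _rmsd_over(m.select(ids), ensemble.reference.select(ids)),
            })
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("region", sort=False)["rmsd_A"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return table, summary


@dataclass(frozen=True)
class ClusterSet:
    """Result of dynamic RMSD clustering."""

    centroids: tuple[str, ...]
    assignment: pd.DataFrame  # columns: member, centroid, rmsd_A
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def _region_distance(
    member: StructureModel,
    centroid: StructureModel,
    shared: np.ndarray,
    region_ids: np.ndarray,
    mode: str,
    regions: RegionSet,
) -> float:
    moved, _ = superpose(member, centroid, shared)
    if mode == "concatenated":
        return _rmsd_over(moved.select(region_ids), centroid.select(region_ids))
    # per-region variant: a prediction is "far" if any single region exceeds
    # the cutoff, so the decision statistic is the max per-region RMSD
    return max(
        _rmsd_over(moved.select(ids), centroid.select(ids))
        for reg in regions
        for ids in [np.intersect1d(reg.residue_ids, shared)]
        if ids.size
    )


def dynamic_cluster(
    ensemble: Ensemble,
    regions: RegionSet | None = None,
    cutoff: float = 3.0,
    mode: Literal["concatenated", "per_region_max"] = "concatenated",
) -> ClusterSet:
    """Greedy leader clustering on the flexible-region RMSD.

    Members are visited in rank order; the top-ranked prediction seeds the
    centroid list.  For each later prediction, the Cα RMSD over the
    concatenated flexible regions is computed against every current centroid
    (after global superposition onto that centroid); if the minimum exceeds
    the cutoff the prediction becomes a new centroid.  Every member is
    finally assigned to its nearest centroid, so each member lies within the
    cutoff of its centroid or is a centroid itself.
    """
    regions = regions or DEFAULT_REGIONS
    shared = ensemble.shared_residue_ids
    region_ids = np.intersect1d(regions.all_residue_ids, shared)
    if region_ids.size == 0:
        raise StructureError("no region residues within the shared span")
    ordered = ensemble.by_rank()
    centroids = [ordered[0]]
    for member in ordered[1:]:
        dmin = min(
            _region_distance(member, c, shared, region_ids, mode, regions)
            for c in centroids
        )
        if dmin > cutoff:
            centroids.append(member)
    centroid_labels = {c.label for c in centroids}
    rows = []
    for member in ordered:
        if member.label in centroid_labels:
            rows.append({"member": member.label, "centroid": member.label, "rmsd_A": 0.0})
            continue
        dists = [
            (_region_distance(member, c, shared, region_ids, mode, regions), c.label)
            for c in centroids
        ]
        d, lab = min(dists)
        rows.append({"member": member.label, "centroid": lab, "rmsd_A": d})
    return ClusterSet(tuple(c.label for c in centroids), pd.DataFrame(rows), cutoff)
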