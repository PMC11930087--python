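"""Superposition, RMSF, region RMSD and dynamic (leader) clustering."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import porlab as pl
from porlab.simulate_ensemble import EnsembleDesign, sample_ensemble
from porlab.structure import StructureError

from oracles import numeric_superpose_rmsd


def rigid_copy(model, seed=0, angle=None):
    rng = np.random.default_rng(seed)
    rot = (
        Rotation.from_rotvec(angle) if angle is not None else Rotation.random(rng=rng)
    )
    return dataclasses.replace(
        model, coords=rot.apply(model.coords) + rng.normal(0, 20, 3)
    )


class TestSuperpose:
    def test_identical_models_rmsd_zero(self, reference_trace):
        _, rmsd = pl.superpose(reference_trace, reference_trace)
        assert rmsd <= 1e-10

    def test_rigid_transform_recovered_exactly(self, reference_trace):
        moved = rigid_copy(reference_trace, angle=np.deg2rad([37.0, 0.0, 0.0]))
        fitted, rmsd = pl.superpose(moved, reference_trace)
        assert rmsd <= 1e-10
        np.testing.assert_allclose(fitted.coords, reference_trace.coords, atol=1e-8)

    def test_symmetric_under_swap(self, reference_trace):
        other = dataclasses.replace(
            reference_trace,
            coords=reference_trace.coords
            + np.random.default_rng(3).normal(0, 1, reference_trace.coords.shape),
        )
        _, ab = pl.superpose(other, reference_trace)
        _, ba = pl.superpose(reference_trace, other)
        assert ab == pytest.approx(ba, abs=1e-8)

    def test_invariant_to_rigid_pretransform_of_mobile(self, reference_trace):
        other = dataclasses.replace(
            reference_trace,
            coords=reference_trace.coords
            + np.random.default_rng(4).normal(0, 1, reference_trace.coords.shape),
        )
        _, direct = pl.superpose(other, reference_trace)
        _, pre = pl.superpose(rigid_copy(other, seed=9), reference_trace)
        assert direct == pytest.approx(pre, abs=1e-8)

    def test_agrees_with_numeric_minimizer_oracle(self):
        """50-residue toy, one atom displaced 3 Å: Kabsch result matches a
        generic numeric optimization over rotations and translations."""
        rng = np.random.default_rng(17)
        ref_coords = rng.normal(0, 8, (50, 3))
        mob_coords = ref_coords.copy()
        mob_coords[25] += np.array([3.0, 0.0, 0.0])
        ref = pl.StructureModel(np.arange(50), ref_coords)
        mob = pl.StructureModel(np.arange(50), mob_coords)
        _, rmsd = pl.superpose(mob, ref)
        oracle = numeric_superpose_rmsd(mob_coords, ref_coords)
        assert rmsd == pytest.approx(oracle, abs=1e-4)

    def test_agrees_with_mdanalysis_rotation_fit(self):
        """Cross-check against the MD toolchain's own Kabsch implementation."""
        from MDAnalysis.analysis.align import rotation_matrix

        rng = np.random.default_rng(21)
        ref_coords = rng.normal(0, 8, (60, 3))
        mob_coords = ref_coords + rng.normal(0, 0.7, (60, 3))
        ref = pl.StructureModel(np.arange(60), ref_coords)
        mob = pl.StructureModel(np.arange(60), mob_coords)
        _, rmsd = pl.superpose(mob, ref)
        _, mda_rmsd = rotation_matrix(
            mob_coords - mob_coords.mean(axis=0), ref_coords - ref_coords.mean(axis=0)
        )
        assert rmsd == pytest.approx(mda_rmsd, abs=1e-8)

    def test_degenerate_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        a = pl.StructureModel(np.arange(5), line)
        with pytest.raises(StructureError, match="collinear|degenerate"):
            pl.superpose(a, a)


class TestRMSF:
    def test_identical_members_rmsf_zero(self, reference_trace):
        members = [
            dataclasses.replace(rigid_copy(reference_trace, seed=s), rank=s, label=f"m{s}")
            for s in range(4)
        ]
        table = pl.rmsf(pl.Ensemble(tuple(members), reference_trace))
        assert np.all(table.rmsf_A < 1e-8)

    def test_two_member_displacement_gives_delta(self, reference_trace):
        delta = 0.8
        up = reference_trace.coords.copy()
        dn = reference_trace.coords.copy()
        up[100, 0] += delta
        dn[100, 0] -= delta
        members = (
            pl.StructureModel(reference_trace.residue_ids, up, 0, "up"),
            pl.StructureModel(reference_trace.residue_ids, dn, 1, "dn"),
        )
        table = pl.rmsf(pl.Ensemble(members, reference_trace))
        # residue 101 (0-based row 100) fluctuates ±delta about the mean
        val = float(table.loc[table.residue == 101, "rmsf_A"].iloc[0])
        assert val == pytest.approx(delta, rel=0.02)

    def test_fewer_than_two_members_rejected(self, reference_trace):
        with pytest.raises(StructureError):
            pl.rmsf(pl.Ensemble((reference_trace,), reference_trace))

    def test_localized_jitter_recovered(self, reference_trace):
        design = EnsembleDesign(n_members=200, jitter_sigma={"helix_a10": 1.0}, seed=2)
        ensemble, _ = sample_ensemble(design, reference_trace)
        table = pl.rmsf(ensemble)
        in_region = (table.residue >= 316) & (table.residue <= 338)
        expected = np.sqrt(3.0)  # isotropic sigma=1 per axis
        assert table[in_region].rmsf_A.mean() == pytest.approx(expected, rel=0.10)
        assert table[~in_region].rmsf_A.mean() < 0.2 * expected

    def test_about_reference_exceeds_about_mean(self, reference_trace):
        design = EnsembleDesign(
            n_members=50, jitter_sigma=0.3,
            family_offsets=[{"helix_a10": 2.0}], family_fractions=[1.0], seed=5,
        )
        ensemble, _ = sample_ensemble(design, reference_trace)
        about_mean = pl.rmsf(ensemble, about="mean")
        about_ref = pl.rmsf(ensemble, about="reference")
        helix = (about_mean.residue >= 316) & (about_mean.residue <= 338)
        assert (
            about_ref[helix].rmsf_A.mean() > about_mean[helix].rmsf_A.mean() + 1.0
        )


class TestRegionRMSD:
    def test_reference_member_scores_zero(self, reference_trace):
        members = (
            dataclasses.replace(reference_trace, rank=0, label="ref_copy"),
            rigid_copy(reference_trace, seed=1),
        )
        members = (members[0], dataclasses.replace(members[1], rank=1, label="rc"))
        table, _ = pl.region_rmsd(pl.Ensemble(members, reference_trace))
        assert np.all(table[table.member == "ref_copy"].rmsd_A < 1e-8)

    def test_displaced_helix_detected_only_there(self, reference_trace):
        coords = reference_trace.coords.copy()
        mask = (reference_trace.residue_ids >= 316) & (reference_trace.residue_ids <= 338)
        coords[mask] += np.array([5.0, 0.0, 0.0])
        member = pl.StructureModel(reference_trace.residue_ids, coords, 0, "disp")
        other = dataclasses.replace(reference_trace, rank=1, label="same")
        table, _ = pl.region_rmsd(pl.Ensemble((member, other), reference_trace))
        disp = table[table.member == "disp"].set_index("region").rmsd_A
        # the global fit absorbs part of a localized displacement (rotation
        # leakage), so the region RMSD sits somewhat below the planted 5 A
        assert disp["helix_a10"] == pytest.approx(5.0, rel=0.20)
        assert disp[["pchlide_loop", "interface_I", "interface_II"]].max() < 1.0

    def test_two_family_distribution_is_separated(self, two_family_ensemble):
        """The planted families produce two well-separated RMSD components in
        the displaced region (bimodality of the region-RMSD distribution)."""
        ensemble, truth = two_family_ensemble
        table, _ = pl.region_rmsd(ensemble)
        sub = table[table.region == "interface_II"].merge(
            truth, left_on="member", right_on="member"
        )
        g0 = sub[sub.family == 0].rmsd_A
        g1 = sub[sub.family == 1].rmsd_A
        gap = abs(g1.mean() - g0.mean())
        spread = max(g0.std(), g1.std())
        assert gap > 4 * spread

    def test_summary_quartiles(self, two_family_ensemble):
        ensemble, _ = two_family_ensemble
        table, summary = pl.region_rmsd(ensemble)
        row = summary[summary.region == "interface_II"].iloc[0]
        vals = table[table.region == "interface_II"].rmsd_A
        assert row["median"] == pytest.approx(vals.median())
        assert row.q1 <= row["median"] <= row.q3


class TestDynamicCluster:
    def test_tight_ensemble_single_centroid(self, reference_trace):
        design = EnsembleDesign(n_members=15, jitter_sigma=0.1, seed=4)
        ensemble, _ = sample_ensemble(design, reference_trace)
        clusters = pl.dynamic_cluster(ensemble, cutoff=3.0)
        assert clusters.n_clusters == 1
        assert clusters.centroids[0] == "model_0"  # seeded by top rank

    def test_two_planted_families_two_pure_centroids(self, two_family_ensemble):
        ensemble, truth = two_family_ensemble
        clusters = pl.dynamic_cluster(ensemble, cutoff=3.0)
        assert clusters.n_clusters == 2
        fam = dict(zip(truth.member, truth.family))
        centroid_fam = {c: fam[c] for c in clusters.centroids}
        assert all(
            fam[row.member] == centroid_fam[row.centroid]
            for row in clusters.assignment.itertuples()
        )

    def test_huge_cutoff_one_centroid_zero_cutoff_all(self, two_family_ensemble):
        ensemble, _ = two_family_ensemble
        assert pl.dynamic_cluster(ensemble, cutoff=1e6).n_clusters == 1
        zero = pl.dynamic_cluster(ensemble, cutoff=0.0)
        assert zero.n_clusters == len(ensemble.members)

    def test_invariant_holds_under_member_permutation(self, two_family_ensemble):
        """Permuting non-top members may change centroids but every member
        stays within the cutoff of its assigned centroid."""
        ensemble, _ = two_family_ensemble
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = np.concatenate([[0], 1 + rng.permutation(len(ensemble.members) - 1)])
            reranked = tuple(
                dataclasses.replace(ensemble.members[j], rank=i)
                for i, j in enumerate(perm)
            )
            clusters = pl.dynamic_cluster(
                pl.Ensemble(reranked, ensemble.reference), cutoff=3.0
            )
            assert np.all(clusters.assignment.rmsd_A <= 3.0 + 1e-9)

    def test_per_region_mode_at_least_as_many_centroids(self, two_family_ensemble):
        """A max-over-regions distance is >= the concatenated RMSD, so the
        per-region variant can only split clusters further."""
        ensemble, _ = two_family_ensemble
        concat = pl.dynamic_cluster(ensemble, cutoff=3.0, mode="concatenated")
        per = pl.dynamic_cluster(ensemble, cutoff=3.0, mode="per_region_max")
        assert per.n_clusters >= concat.n_clusters
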