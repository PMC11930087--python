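"""Oligomerization index, lipid optimum and emission-maximum pairing."""

import math

import numpy as np
import pytest

import porlab as pl
from porlab.maxima import IndexError_, index_series, pairs_frame

from oracles import gaussian_mixture_intensity


def two_band_spectrum(a655=1.0, a632=0.2):
    return pl.normalize(
        pl.render_spectrum(
            [pl.SpectralBand(655.0, 6.0, a655), pl.SpectralBand(632.0, 6.0, a632)]
        )
    )


class TestOligoIndex:
    def test_equal_intensities_give_zero(self):
        spec = pl.Spectrum(pl.default_grid(), np.ones(381))
        assert pl.oligo_index(spec, "NADPH") == 0.0

    def test_swapping_wavelengths_negates(self):
        spec = two_band_spectrum()
        forward = pl.oligo_index(spec, numerator_nm=658.0, denominator_nm=631.0)
        backward = pl.oligo_index(spec, numerator_nm=631.0, denominator_nm=658.0)
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_matches_closed_form_gaussian_oracle(self):
        bands = [(655.0, 6.0, 0.8), (632.0, 6.0, 0.3)]
        spec = pl.render_spectrum([pl.SpectralBand(*b) for b in bands])
        expected = math.log10(
            gaussian_mixture_intensity(bands, 658.0)
            / gaussian_mixture_intensity(bands, 631.0)
        )
        assert pl.oligo_index(spec, "NADPH") == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self):
        spec = two_band_spectrum()
        scaled = pl.Spectrum(spec.wavelengths, spec.intensities * 13.0)
        assert pl.oligo_index(spec, "NADPH") == pytest.approx(
            pl.oligo_index(scaled, "NADPH"), abs=1e-12
        )

    def test_nadp_variant_uses_647(self):
        bands = [(647.0, 6.0, 0.8), (632.0, 6.0, 0.3)]
        spec = pl.render_spectrum([pl.SpectralBand(*b) for b in bands])
        expected = math.log10(
            gaussian_mixture_intensity(bands, 647.0)
            / gaussian_mixture_intensity(bands, 631.0)
        )
        assert pl.oligo_index(spec, "NADP+") == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_intensity_rejected(self):
        spec = pl.Spectrum(pl.default_grid(), np.zeros(381))
        with pytest.raises(IndexError_):
            pl.oligo_index(spec, "NADPH")


class TestLipidOptimum:
    CONCS = [2.0, 5.0, 10.0, 20.0, 40.0, 100.0, 200.0, 400.0]

    def test_planted_unimodal_optimum_recovered(self):
        params = pl.GeneratorParams(noise_sigma=0.0, seed=2)
        spectra = pl.simulate_lipid_titration(self.CONCS, 100.0, params, replicates=1)
        series = index_series(spectra, "NADPH")
        opt, shape = pl.lipid_optimum(series)
        assert opt == 100.0
        assert shape == "concave_down"

    def test_strictly_increasing_series_is_monotone(self):
        series = pl.OligoIndexSeries(np.array(self.CONCS), np.linspace(0, 1, 8))
        opt, shape = pl.lipid_optimum(series)
        assert opt == 400.0
        assert shape == "monotone_increasing"

    def test_all_equal_series_is_flat_with_lowest_conc(self):
        series = pl.OligoIndexSeries(np.array(self.CONCS), np.zeros(8))
        opt, shape = pl.lipid_optimum(series)
        assert opt == 2.0
        assert shape == "flat"

    def test_too_few_points_rejected(self):
        series = pl.OligoIndexSeries(np.array([2.0, 10.0, 40.0]), np.zeros(3))
        with pytest.raises(ValueError):
            pl.lipid_optimum(series)


def maxima_samples(nadph, seed=0, **kw):
    return pl.simulate_maxima_dataset(nadph, seed=seed, **kw)


class TestPairMaxima:
    def test_all_below_threshold_yields_no_pairs(self):
        pairs, report = pl.pair_maxima(maxima_samples([0.0625] * 10))
        assert pairs == [] and report["n_below_threshold"] == 10

    def test_constructed_37_of_50_manifest(self):
        nadph = [0.0625] * 13 + list(np.linspace(1.0, 200.0, 37))
        pairs, report = pl.pair_maxima(maxima_samples(nadph))
        assert len(pairs) == 37
        assert report["n_input"] == 50
        assert report["n_retained"] + report["n_below_threshold"] == 50

    def test_threshold_is_inclusive_at_1_uM(self):
        pairs, _ = pl.pair_maxima(maxima_samples([1.0]))
        assert len(pairs) == 1

    def test_nadp_samples_never_enter(self):
        samples = maxima_samples([4.0, 8.0])
        samples[0].meta["dinucleotide"] = "NADP+"
        pairs, report = pl.pair_maxima(samples)
        assert len(pairs) == 1 and report["n_wrong_dinucleotide"] == 1

    def test_orphan_dark_skipped_with_warning(self):
        import dataclasses

        samples = maxima_samples([4.0, 8.0])
        samples[1] = dataclasses.replace(samples[1], illuminated=None)
        with pytest.warns(UserWarning, match="illuminated"):
            pairs, report = pl.pair_maxima(samples)
        assert len(pairs) == 1 and report["n_orphan"] == 1

    def test_pairs_frame_columns(self):
        pairs, _ = pl.pair_maxima(maxima_samples([4.0]))
        df = pairs_frame(pairs)
        assert {"pchlide_max_nm", "chlide_max_nm", "nadph_uM"} <= set(df.columns)


class TestHistograms:
    def test_single_pair_one_bin_per_axis(self):
        pairs, _ = pl.pair_maxima(maxima_samples([4.0]))
        hist = pl.maxima_histograms(pairs)
        assert hist["pchlide"]["counts"].sum() == 1
        assert (hist["pchlide"]["counts"] > 0).sum() == 1
        assert (hist["chlide"]["counts"] > 0).sum() == 1

    def test_mass_conservation_overall_and_per_isoform(self):
        pairs, _ = pl.pair_maxima(maxima_samples(np.linspace(1, 200, 60), seed=3))
        hist = pl.maxima_histograms(pairs)
        for axis in ("pchlide", "chlide"):
            counts = hist[axis]["counts"]
            assert counts.sum() == len(pairs)
            stacked = sum(hist[axis]["per_isoform"].values())
            np.testing.assert_array_equal(stacked, counts)

    def test_three_planted_classes_recovered_as_modes(self):
        pairs, _ = pl.pair_maxima(maxima_samples(np.linspace(1, 200, 300), seed=5))
        hist = pl.maxima_histograms(pairs)
        counts, edges = hist["pchlide"]["counts"], hist["pchlide"]["edges"]
        occupied = edges[:-1][counts > 0]
        for center in (637.0, 648.0, 655.0):
            assert np.any(np.abs(occupied - center) <= 1.0)


class TestConditionalChlide:
    def test_empty_subset_returns_explicit_empty(self):
        pairs, _ = pl.pair_maxima(
            maxima_samples([4.0] * 5, class_weights=(0.0, 1.0, 0.0))
        )
        result = pl.conditional_chlide(pairs, 637.0)
        assert result.n == 0 and result.mode is None

    def test_selection_idempotent_and_order_invariant(self):
        pairs, _ = pl.pair_maxima(maxima_samples(np.linspace(1, 200, 40), seed=9))
        a = pl.conditional_chlide(pairs, 648.0)
        b = pl.conditional_chlide(list(reversed(pairs)), 648.0)
        assert sorted(a.chlide_maxima) == sorted(b.chlide_maxima)
        assert a.mode == b.mode

    @pytest.mark.parametrize("center,coupled", [(637.0, 681.0), (648.0, 683.0), (655.0, 687.0)])
    def test_generator_couplings_recovered_as_conditional_modes(self, center, coupled):
        pairs, _ = pl.pair_maxima(maxima_samples(np.linspace(1, 200, 400), seed=13))
        result = pl.conditional_chlide(pairs, center, halfwidth=2.5)
        assert result.n > 0
        assert result.mode == coupled
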