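"""Readout-level operations: histograms, subpopulations, FLIRR, rendering."""

import numpy as np
import pytest

import flimox as fx
from flimox.calibration import OxygenMap
from flimox.decay import FitImage


def _uniform_fit(shape=(8, 8), tau=1.5, a1=0.3, mask=None):
    h, w = shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    full = np.where(mask, 1.0, np.nan)
    return FitImage(
        tau1=0.6 * full, tau2=((tau - a1 * 0.6) / (1 - a1)) * full,
        a1=a1 * full, a2=(1 - a1) * full, tau_mean=tau * full,
        chi2_reduced=1.0 * full, photons=np.full(shape, 5000.0),
        mask=mask, chi2_flag=np.zeros(shape, dtype=bool))


def _oxygen_map(values, condition=""):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return OxygenMap(po2=values, mask=np.isfinite(values),
                     saturated_mask=np.zeros_like(values, dtype=bool),
                     condition=condition)


class TestLifetimeHistogram:
    def test_constant_image_single_bin(self):
        hist = fx.lifetime_histogram(_uniform_fit(tau=1.5), bin_width=0.05)
        assert np.count_nonzero(hist.frequencies) == 1
        assert hist.frequencies.max() == pytest.approx(1.0)

    def test_frequencies_normalized(self, small_scene_fit):
        *_rest, fit = small_scene_fit
        hist = fx.lifetime_histogram(fit, bin_width=0.05)
        assert hist.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(hist.bin_edges) > 0)

    def test_refinement_consistency(self, small_scene_fit):
        """Halving the bin width re-aggregates exactly to the coarse histogram."""
        *_rest, fit = small_scene_fit
        coarse = fx.lifetime_histogram(fit, bin_width=0.1)
        fine = fx.lifetime_histogram(fit, bin_width=0.05)
        # align fine bins onto the coarse grid and re-sum
        reagg = {}
        for edge, freq in zip(fine.bin_edges[:-1], fine.frequencies):
            key = np.floor(round(edge / 0.1, 9))
            reagg[key] = reagg.get(key, 0.0) + freq
        for edge, freq in zip(coarse.bin_edges[:-1], coarse.frequencies):
            key = np.floor(round(edge / 0.1, 9))
            assert reagg.get(key, 0.0) == pytest.approx(freq, abs=1e-12)

    def test_mixture_shift_between_conditions(self):
        """The low-OCR-dominated condition carries more long-lifetime mass."""
        hists = {}
        for name, mix in (("WT", fx.WT_MIXTURE), ("KO", fx.KO_MIXTURE)):
            spec = fx.SceneSpec(image_height=64, image_width=64, mito_count=8,
                                mito_radius_range=(2, 3.5), po2_mixture=mix,
                                condition=name, seed=23)
            image, _truth = fx.generate_decay_image(spec)
            fit = fx.fit_image(image, spatial_binning=3, channel_rebin=4)
            hists[name] = fx.lifetime_histogram(fit, bin_width=0.05)
        midpoint = 0.5 * (0.914 + 2.5)
        assert hists["KO"].mass_above(midpoint) > hists["WT"].mass_above(midpoint)

    def test_empty_selection_rejected(self):
        fit = _uniform_fit(mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            fx.lifetime_histogram(fit)


class TestSubpopulationFractions:
    def test_all_zero_po2_is_all_high_ocr(self):
        summary = fx.subpopulation_fractions(_oxygen_map(np.zeros((4, 4))), 10.0, 30.0)
        assert summary.high_ocr_fraction == 1.0
        assert summary.mid_fraction == pytest.approx(0.0)

    def test_thresholds_outside_range_all_mid(self):
        summary = fx.subpopulation_fractions(
            _oxygen_map(np.full((4, 4), 20.0)), 5.0, 100.0)
        assert summary.mid_fraction == 1.0

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 80, size=200)
        a = fx.subpopulation_fractions(_oxygen_map(values), 20.0, 45.0)
        b = fx.subpopulation_fractions(_oxygen_map(rng.permutation(values)), 20.0, 45.0)
        assert a.high_ocr_fraction + a.low_ocr_fraction + a.mid_fraction == \
            pytest.approx(1.0, abs=1e-9)
        assert a.high_ocr_fraction == b.high_ocr_fraction
        assert a.low_ocr_fraction == b.low_ocr_fraction

    def test_masked_pixels_do_not_count(self):
        values = np.array([[0.0, 0.0, np.nan, np.nan]])
        summary = fx.subpopulation_fractions(_oxygen_map(values), 10.0, 30.0)
        assert summary.n_pixels == 2
        assert summary.high_ocr_fraction == 1.0

    def test_simulated_mixture_fraction_near_weight(self, small_scene_fit):
        """WT-like scene: ~60% of mitochondrial pixels sit in the low-pO2 mode."""
        spec, _image, truth, fit = small_scene_fit
        omap = fx.po2_map(fit, spec.truth_calibration())
        summary = fx.subpopulation_fractions(omap, 30.0, 40.0)
        true_po2 = np.array([truth.per_mito_po2[l]
                             for l in truth.mito_label_image[truth.mito_mask()]])
        truth_frac = np.mean(true_po2 <= 30.0)
        assert summary.high_ocr_fraction == pytest.approx(truth_frac, abs=0.05)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            fx.subpopulation_fractions(_oxygen_map(np.zeros((2, 2))), 30.0, 10.0)


class TestReferenceThresholds:
    def test_percentiles_of_reference(self):
        values = np.arange(101, dtype=float)
        lo, hi = fx.reference_thresholds(values)
        assert lo == pytest.approx(25.0)
        assert hi == pytest.approx(75.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            fx.reference_thresholds(np.array([np.nan]))


class TestFlirrMap:
    def test_constant_ratio(self):
        nadh = _uniform_fit(a1=0.6)   # bound NAD(P)H fraction a2 = 40%
        fad = _uniform_fit(a1=0.2)    # bound FAD fraction a1 = 20%
        redox = fx.flirr_map(nadh, fad)
        np.testing.assert_allclose(redox.valid_values, 2.0)

    def test_zero_fad_fraction_masked(self):
        nadh = _uniform_fit()
        fad = _uniform_fit(a1=0.2)
        fad.a1[0, 0] = 0.0
        redox = fx.flirr_map(nadh, fad)
        assert not redox.mask[0, 0]
        assert np.isnan(redox.flirr[0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fx.flirr_map(_uniform_fit((8, 8)), _uniform_fit((8, 9)))

    def test_simulated_truth_ratio(self):
        """NAD(P)H-like a2=60% over FAD-like a1=40% gives FLIRR 1.5."""
        nadh_spec = fx.SceneSpec(image_height=48, image_width=48, mito_count=6,
                                 mito_radius_range=(2, 3.5), short_fraction=0.4,
                                 seed=29)
        fad_spec = fx.SceneSpec(image_height=48, image_width=48, mito_count=6,
                                mito_radius_range=(2, 3.5), short_fraction=0.4,
                                seed=29)
        nadh_img, _ = fx.generate_decay_image(nadh_spec)
        fad_img, _ = fx.generate_decay_image(fad_spec)
        nadh_fit = fx.fit_image(nadh_img, spatial_binning=3, channel_rebin=4)
        fad_fit = fx.fit_image(fad_img, spatial_binning=3, channel_rebin=4)
        redox = fx.flirr_map(nadh_fit, fad_fit)
        assert np.median(redox.valid_values) == pytest.approx(1.5, rel=0.05)


class TestRenderPseudocolor:
    def test_warm_to_cool_orientation(self, tmp_path):
        from PIL import Image
        omap = _oxygen_map(np.array([[0.0, 80.0]]))
        meta = fx.render_pseudocolor(omap, tmp_path / "map.png")
        rgb = np.asarray(Image.open(tmp_path / "map.png"))
        low, high = rgb[0, 0].astype(int), rgb[0, 1].astype(int)
        assert low[0] - low[2] > 0          # low pO2: red dominates blue
        assert high[2] - high[0] > 0        # high pO2: blue dominates red
        assert meta["vmin"] == 0.0 and meta["vmax"] == 80.0

    def test_masked_pixels_black_and_deterministic(self, tmp_path):
        values = np.array([[10.0, np.nan], [40.0, 70.0]])
        omap = _oxygen_map(values)
        fx.render_pseudocolor(omap, tmp_path / "a.png", vmin=0, vmax=100)
        fx.render_pseudocolor(omap, tmp_path / "b.png", vmin=0, vmax=100)
        a = (tmp_path / "a.png").read_bytes()
        assert a == (tmp_path / "b.png").read_bytes()
        from PIL import Image
        rgb = np.asarray(Image.open(tmp_path / "a.png"))
        np.testing.assert_array_equal(rgb[0, 1], [0, 0, 0])

    def test_empty_mask_rejected(self, tmp_path):
        omap = _oxygen_map(np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            fx.render_pseudocolor(omap, tmp_path / "x.png")
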