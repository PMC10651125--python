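"""Conditioning chain: despiking, baselines, normalization, grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retispec.preprocess import (BaselineConfig, area_normalize, crop_region,
                                 despike_median, preprocess_map,
                                 remove_cosmic_rays, resample_unit_grid,
                                 snv_normalize, subtract_baseline)
from retispec.spectra import Spectrum, SpectralMap


def _flat_map(n=5, c=200, value=1.0):
    axis = np.arange(2800.0, 2800.0 + c)
    inten = np.full((n, c), value)
    # add a gentle band so spectra are not constant
    inten += 0.5 * np.exp(-0.5 * ((axis - 2900.0) / 15.0) ** 2)
    return SpectralMap(axis, inten)


class TestCosmicRayRemoval:
    def test_single_spike_restored_exactly(self):
        smap = _flat_map()
        corrupted = smap.intensities.copy()
        clean_value = corrupted[2, 50]
        corrupted[2, 50] *= 30.0
        out = remove_cosmic_rays(SpectralMap(smap.axis, corrupted))
        assert out.intensities[2, 50] == pytest.approx(clean_value, rel=0.05)
        # every other channel is bit-identical
        mask = np.ones_like(corrupted, dtype=bool)
        mask[2, 50] = False
        np.testing.assert_array_equal(out.intensities[mask], corrupted[mask])

    def test_clean_map_is_untouched(self):
        smap = _flat_map()
        out = remove_cosmic_rays(smap)
        np.testing.assert_array_equal(out.intensities, smap.intensities)

    def test_two_spikes_in_different_spectra(self):
        smap = _flat_map()
        corrupted = smap.intensities.copy()
        targets = [(1, 30), (3, 120)]
        expected = {t: corrupted[t] for t in targets}
        for t in targets:
            corrupted[t] *= 25.0
        out = remove_cosmic_rays(SpectralMap(smap.axis, corrupted))
        for t in targets:
            assert out.intensities[t] == pytest.approx(expected[t], rel=0.05)

    def test_spatial_neighbors_used_when_positions_present(self):
        smap = _flat_map(n=4)
        meta = pd.DataFrame({"x": [0.0, 10.0, 0.5, 10.5],
                             "y": [0.0, 0.0, 0.0, 0.0]})
        corrupted = smap.intensities.copy()
        corrupted[0, 10] *= 40.0
        out = remove_cosmic_rays(SpectralMap(smap.axis, corrupted, meta))
        assert out.intensities[0, 10] == pytest.approx(
            smap.intensities[0, 10], rel=0.05)

    def test_single_spectrum_map_directs_to_fallback(self):
        smap = _flat_map(n=1)
        with pytest.raises(ValueError, match="despike_median"):
            remove_cosmic_rays(smap)
        spec = smap[0]
        y = spec.intensity.copy()
        y[80] += 50.0
        fixed = despike_median(spec.with_intensity(y))
        assert fixed.intensity[80] == pytest.approx(spec.intensity[80], rel=0.05)


class TestBaseline:
    def test_polynomial_baseline_annihilated_exactly(self):
        x = np.linspace(500.0, 3500.0, 800)
        coeffs = [1.0, 2e-3, -1e-6, 3e-10, -2e-13, 1e-17, 0.0, 0.0, 0.0, 1e-30]
        y = np.polynomial.polynomial.polyval(x - 2000.0, coeffs)
        corrected, base = subtract_baseline(Spectrum(x, y))
        assert np.max(np.abs(corrected.intensity)) < 1e-6 * np.max(np.abs(y))

    def test_band_height_recovered_over_polynomial_baseline(self):
        x = np.linspace(500.0, 3500.0, 1200)
        band = 2.0 * np.exp(-0.5 * ((x - 2930.0) / 20.0) ** 2)
        baseline = 5.0 + 3e-3 * (x - 500.0) - 5e-7 * (x - 500.0) ** 2
        corrected, _ = subtract_baseline(Spectrum(x, band + baseline))
        height = corrected.intensity[np.abs(x - 2930.0) < 15.0].max()
        assert height == pytest.approx(2.0, rel=0.05)

    def test_spline_baseline_tracks_smooth_background(self):
        x = np.linspace(500.0, 3500.0, 1200)
        band = 2.0 * np.exp(-0.5 * ((x - 1660.0) / 15.0) ** 2)
        baseline = 4.0 * np.exp(-0.5 * ((x - 1200.0) / 900.0) ** 2)
        corrected, fitted = subtract_baseline(
            Spectrum(x, band + baseline), BaselineConfig(method="spline"))
        # fitted baseline stays close to the true background away from the band
        off_band = np.abs(x - 1660.0) > 150.0
        assert np.median(np.abs(fitted.intensity - baseline)[off_band]) < 0.4

    def test_zero_spectrum_maps_to_zero(self):
        x = np.linspace(500.0, 3500.0, 300)
        corrected, base = subtract_baseline(Spectrum(x, np.zeros_like(x)))
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-12)
        np.testing.assert_allclose(base.intensity, 0.0, atol=1e-12)

    def test_too_short_spectrum_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            subtract_baseline(Spectrum(x, x))


class TestNormalization:
    def test_snv_zero_mean_unit_sd(self, rng):
        s = Spectrum(np.arange(100.0), rng.normal(3.0, 2.0, 100))
        out = snv_normalize(s)
        assert out.intensity.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.intensity.std() == pytest.approx(1.0, rel=1e-12)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-20.0, 20.0))
    def test_snv_affine_invariance(self, a, b):
        y = np.sin(np.linspace(0.0, 7.0, 64))
        s = Spectrum(np.arange(64.0), y)
        t = Spectrum(np.arange(64.0), a * y + b)
        np.testing.assert_allclose(snv_normalize(s).intensity,
                                   snv_normalize(t).intensity, atol=1e-8)

    def test_snv_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv_normalize(Spectrum(np.arange(10.0), np.full(10, 3.0)))

    def test_area_closed_form(self):
        # constant 2 over a span of 1 cm^-1: integral 2 -> output constant 1
        s = Spectrum(np.array([100.0, 101.0]), np.array([2.0, 2.0]))
        out = area_normalize(s)
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_area_unit_integral_and_idempotence(self, rng):
        s = Spectrum(np.arange(500.0, 900.0, 0.7),
                     rng.uniform(0.5, 2.0, 572))
        out = area_normalize(s)
        assert np.trapezoid(out.intensity, out.axis) == pytest.approx(
            1.0, rel=1e-10)
        again = area_normalize(out)
        np.testing.assert_allclose(again.intensity, out.intensity, rtol=1e-12)

    def test_area_nonpositive_integral_rejected(self):
        s = Spectrum(np.arange(10.0), np.linspace(-1.0, 1.0, 10) - 0.5)
        with pytest.raises(ValueError):
            area_normalize(s)


class TestGrids:
    def test_integer_axis_is_fixed_point(self):
        s = Spectrum(np.arange(500.0, 600.0), np.random.default_rng(0).random(100))
        out = resample_unit_grid(s)
        np.testing.assert_array_equal(out.axis, s.axis)
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_linear_ramp_interpolated_exactly(self):
        x = np.linspace(500.3, 520.9, 40)
        s = Spectrum(x, 2.0 * x + 1.0)
        out = resample_unit_grid(s)
        np.testing.assert_allclose(out.intensity, 2.0 * out.axis + 1.0, rtol=1e-12)

    def test_endpoints_stay_inside_support(self):
        x = np.linspace(500.4, 3499.6, 5000)
        out = resample_unit_grid(Spectrum(x, np.ones_like(x)))
        assert out.axis[0] == 501.0 and out.axis[-1] == 3499.0

    def test_too_narrow_span_rejected(self):
        with pytest.raises(ValueError):
            resample_unit_grid(Spectrum(np.array([100.0, 101.2]),
                                        np.array([1.0, 2.0])))

    def test_crop_bounds_and_identity(self):
        x = np.arange(500.0, 3501.0, 10.0)
        s = Spectrum(x, np.ones_like(x))
        out = crop_region(s, 2800.0, 3200.0)
        assert out.axis.min() >= 2800.0 and out.axis.max() <= 3200.0
        full = crop_region(s, 500.0, 3500.0)
        np.testing.assert_array_equal(full.axis, s.axis)

    def test_crop_outside_support_rejected(self):
        s = Spectrum(np.arange(500.0, 1000.0), np.ones(500))
        with pytest.raises(ValueError):
            crop_region(s, 4000.0, 5000.0)


class TestMapPipeline:
    def test_canonical_chain_shapes(self, small_cohort):
        sub = small_cohort.map.subset(np.arange(8))
        out = preprocess_map(sub, baseline=BaselineConfig(),
                             normalization="snv", region="highwave")
        assert len(out) == 8
        assert out.axis.min() >= 2800.0 and out.axis.max() <= 3200.0
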