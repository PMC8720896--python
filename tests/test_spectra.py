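"""Saturation-weighted hue histograms: computation, averaging, cropping,
peak characterization and CSV round-trips."""

import numpy as np
import pytest

from huespectra import (
    HueSpectrum,
    NonColorImageError,
    average_spectra,
    compute_hue_spectrum,
    crop_spectrum,
    find_peaks,
)
from huespectra.io import read_spectrum_csv, write_spectrum_csv

from conftest import naive_hue_spectrum, uniform_image


def spectrum_from(values, threshold=0.05, n=10):
    return HueSpectrum(values=np.asarray(values, float), n_included=n,
                       threshold_used=threshold, total_pixels=100)


def delta(degree, height=1.0):
    v = np.zeros(360)
    v[degree - 1] = height
    return v


class TestComputeSpectrum:
    def test_uniform_red(self):
        """Every pixel of a pure red image has hue 0 -> bin 360 and
        saturation 1; normalization by the included count gives 1.0."""
        spec = compute_hue_spectrum(uniform_image((255, 0, 0)))
        assert spec.value_at(360) == pytest.approx(1.0, abs=1e-12)
        assert spec.n_included == 100
        assert np.count_nonzero(spec.values) == 1

    def test_uniform_white_nothing_included(self):
        spec = compute_hue_spectrum(uniform_image((255, 255, 255)))
        assert spec.n_included == 0
        assert np.all(spec.values == 0)

    def test_normalization_by_included_not_total(self):
        """Half red / half white: the divisor is the 50 included pixels,
        so the red bin still reads 1.0."""
        img = uniform_image((255, 255, 255))
        img[:5] = (255, 0, 0)
        spec = compute_hue_spectrum(img)
        assert spec.n_included == 50
        assert spec.value_at(360) == pytest.approx(1.0, abs=1e-12)

    def test_prose_normalization_divides_by_total(self):
        img = uniform_image((255, 255, 255))
        img[:5] = (255, 0, 0)
        spec = compute_hue_spectrum(img, normalization="total")
        assert spec.value_at(360) == pytest.approx(0.5, abs=1e-12)

    def test_single_included_pixel_gives_zero_spectrum(self):
        img = uniform_image((255, 255, 255))
        img[0, 0] = (255, 0, 0)
        spec = compute_hue_spectrum(img)
        assert spec.n_included == 1
        assert np.all(spec.values == 0)

    def test_matches_naive_oracle_on_random_images(self, rng):
        """The vectorized pipeline reproduces the per-pixel double-loop
        transliteration bin for bin."""
        for _ in range(8):
            img = rng.integers(0, 256, size=(rng.integers(4, 64), rng.integers(4, 64), 3), dtype=np.uint8)
            expected, n = naive_hue_spectrum(img)
            spec = compute_hue_spectrum(img)
            assert spec.n_included == n
            np.testing.assert_allclose(spec.values, expected, atol=1e-9)

    def test_bin_sum_equals_included_saturation_sum(self, rng):
        from huespectra import rgb_to_hue_sat

        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        spec = compute_hue_spectrum(img)
        _, sat = rgb_to_hue_sat(img)
        assert spec.values.sum() * spec.n_included == pytest.approx(
            sat[sat > 0.05].sum(), abs=1e-9
        )

    def test_threshold_monotonicity(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        counts = [compute_hue_spectrum(img, tv).n_included for tv in (0.0, 0.05, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_tiling_invariance(self, rng):
        """Spectra are normalized by pixel count, so a 2x2 tiling of the
        image leaves every bin unchanged."""
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        tiled = np.tile(img, (2, 2, 1))
        np.testing.assert_allclose(
            compute_hue_spectrum(tiled).values, compute_hue_spectrum(img).values, atol=1e-9
        )

    def test_non_color_image_error(self):
        with pytest.raises(NonColorImageError):
            compute_hue_spectrum(np.zeros((4, 4), dtype=np.uint8))

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            compute_hue_spectrum(uniform_image((255, 0, 0)), threshold=1.0)


class TestAverage:
    def test_idempotent_on_identical_spectra(self):
        s = spectrum_from(delta(120))
        avg = average_spectra([s, s])
        np.testing.assert_allclose(avg.values, s.values)
        assert avg.aggregate

    def test_mean_of_two_deltas(self):
        avg = average_spectra([spectrum_from(delta(360)), spectrum_from(delta(120))])
        assert avg.value_at(360) == pytest.approx(0.5)
        assert avg.value_at(120) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_k_copies_plus_zero_scales_by_k_over_k_plus_1(self, k):
        s = spectrum_from(delta(45, 0.8))
        zero = spectrum_from(np.zeros(360))
        avg = average_spectra([s] * k + [zero])
        np.testing.assert_allclose(avg.values, s.values * k / (k + 1), atol=1e-12)

    def test_empty_and_mixed_threshold_errors(self):
        with pytest.raises(ValueError):
            average_spectra([])
        with pytest.raises(ValueError, match="threshold"):
            average_spectra([spectrum_from(delta(1), 0.05), spectrum_from(delta(1), 0.1)])


class TestCrop:
    def test_full_range_is_identity(self):
        s = spectrum_from(delta(360) + delta(120, 0.5))
        np.testing.assert_array_equal(crop_spectrum(s, 1, 360).values, s.values)

    def test_plain_range_membership(self):
        s = spectrum_from(delta(360) + delta(120, 0.5))
        cropped = crop_spectrum(s, 90, 150)
        assert cropped.value_at(120) == 0.5
        assert cropped.value_at(360) == 0.0
        assert cropped.crop_range == (90, 150)

    def test_wrapped_range_keeps_red_drops_green(self):
        s = spectrum_from(delta(360) + delta(120, 0.5))
        cropped = crop_spectrum(s, 330, 30)
        assert cropped.value_at(360) == 1.0
        assert cropped.value_at(120) == 0.0

    def test_against_brute_force_membership(self, rng):
        values = rng.uniform(0, 1, 360)
        s = spectrum_from(values)
        for lo, hi in [(1, 360), (45, 300), (330, 30), (200, 100), (7, 7)]:
            cropped = crop_spectrum(s, lo, hi)
            for deg in range(1, 361):
                inside = lo <= deg <= hi if lo <= hi else (deg >= lo or deg <= hi)
                assert cropped.value_at(deg) == (values[deg - 1] if inside else 0.0)

    def test_out_of_bounds_error(self):
        with pytest.raises(ValueError):
            crop_spectrum(spectrum_from(delta(1)), 0, 30)
        with pytest.raises(ValueError):
            crop_spectrum(spectrum_from(delta(1)), 10, 361)


class TestFindPeaks:
    def test_triangular_peak_geometry(self):
        v = np.zeros(360)
        v[118:121] = [0.5, 1.0, 0.5]  # degrees 119, 120, 121
        peaks = find_peaks(spectrum_from(v))
        assert len(peaks) == 1
        assert peaks[0].location == 120
        assert peaks[0].height == 1.0
        assert peaks[0].width == pytest.approx(2.0, abs=1e-9)

    def test_all_zero_spectrum_has_no_peaks(self):
        assert find_peaks(spectrum_from(np.zeros(360))) == []

    def test_peak_straddling_the_fold(self):
        """A summit at degree 360 with shoulders at 359 and 1 is found
        once, at 360, thanks to circular adjacency."""
        v = delta(360) + delta(359, 0.4) + delta(1, 0.4)
        peaks = find_peaks(spectrum_from(v))
        assert [p.location for p in peaks] == [360]
        # each flank crosses half height (0.5) between 1.0 and 0.4
        assert peaks[0].width == pytest.approx(2.0 * (1.0 - 0.5) / (1.0 - 0.4), abs=1e-9)

    def test_single_bin_spike_has_unit_width(self):
        peaks = find_peaks(spectrum_from(delta(42)))
        assert peaks[0].width == pytest.approx(1.0, abs=1e-9)

    def test_plateau_reported_once_at_lowest_degree(self):
        v = np.zeros(360)
        v[99:103] = 0.7  # degrees 100..103
        peaks = find_peaks(spectrum_from(v))
        assert [p.location for p in peaks] == [100]

    def test_min_height_filters(self):
        v = delta(50, 0.3) + delta(200, 0.9)
        assert [p.location for p in find_peaks(spectrum_from(v), min_height=0.5)] == [200]

    def test_constant_spectrum_has_no_local_maxima(self):
        assert find_peaks(spectrum_from(np.full(360, 0.5))) == []


def test_spectrum_csv_roundtrip(tmp_path, rng):
    img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    spec = compute_hue_spectrum(img)
    spec = crop_spectrum(spec, 330, 30)
    path = write_spectrum_csv(spec, tmp_path / "s.csv")
    back = read_spectrum_csv(path)
    np.testing.assert_array_equal(back.values, spec.values)
    assert back.n_included == spec.n_included
    assert back.threshold_used == spec.threshold_used
    assert back.total_pixels == spec.total_pixels
    assert back.crop_range == spec.crop_range
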