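"""Spectral processing: FT/apodization, calibration, bucketing, exclusion,
normalization, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ficollnmr as f
from ficollnmr.errors import CalibrationError, NormalizationError
from ficollnmr.spectra import exclusion_mask


def lorentzian(ppm, center, hwhm, amp=1.0):
    return amp * hwhm ** 2 / ((ppm - center) ** 2 + hwhm ** 2)


# ---------------------------------------------------------------------------
# process_fid / synthesize_fid


class TestFIDProcessing:
    def test_round_trip_identity(self, small_axis):
        spec = f.Spectrum(small_axis, lorentzian(small_axis, 5.0, 0.01, 2.0))
        fid = f.synthesize_fid(spec)
        back = f.process_fid(fid, line_broadening=0.0)
        assert np.allclose(back.ppm, spec.ppm, atol=1e-10)
        scale = np.abs(spec.intensity).max()
        assert np.abs(back.intensity - spec.intensity).max() < 1e-8 * scale

    def test_zero_spectrum_gives_zero_fid(self, small_axis):
        fid = f.synthesize_fid(f.Spectrum(small_axis, np.zeros(small_axis.size)))
        assert np.abs(fid.data).max() == 0.0

    def test_n_points_too_small_rejected(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        with pytest.raises(ValueError):
            f.synthesize_fid(spec, n_points=small_axis.size - 1)

    def test_negative_line_broadening_rejected(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        with pytest.raises(ValueError):
            f.process_fid(f.synthesize_fid(spec), line_broadening=-1.0)

    @staticmethod
    def _fwhm_hz(spec, sfreq):
        i = int(np.argmax(spec.intensity))
        half = spec.intensity[i] / 2.0
        above = spec.intensity >= half
        lo, hi = np.flatnonzero(above)[[0, -1]]
        # linear interpolation of the two half-height crossings
        x, y = spec.ppm, spec.intensity
        left = x[lo - 1] + (half - y[lo - 1]) / (y[lo] - y[lo - 1]) * (x[lo] - x[lo - 1])
        right = x[hi] + (half - y[hi]) / (y[hi + 1] - y[hi]) * (x[hi + 1] - x[hi])
        return (right - left) * sfreq

    def test_line_broadening_adds_1hz_and_conserves_integral(self):
        # pure decaying complex exponential -> absorption Lorentzian of FWHM w
        n, sw, sfreq, w = 8192, 2000.0, 600.0, 2.0
        t = np.arange(n) / sw
        data = np.exp(2j * np.pi * 100.0 * t - np.pi * w * t)
        fid = f.FID(data, dwell_time=1.0 / sw, spectrometer_frequency=sfreq,
                    carrier_ppm=5.0)
        raw = f.process_fid(fid, line_broadening=0.0)
        broad = f.process_fid(fid, line_broadening=1.0)
        assert self._fwhm_hz(broad, sfreq) - self._fwhm_hz(raw, sfreq) == pytest.approx(1.0, abs=0.1)
        area_raw = np.trapezoid(raw.intensity, raw.ppm)
        area_broad = np.trapezoid(broad.intensity, broad.ppm)
        assert area_broad == pytest.approx(area_raw, rel=1e-6)


# ---------------------------------------------------------------------------
# calibrate


class TestCalibration:
    def _doublet(self, center, split=0.02, n=16384):
        ppm = np.linspace(0, 10.2, n)
        y = (lorentzian(ppm, center - split / 2, 0.003, 5.0)
             + lorentzian(ppm, center + split / 2, 0.003, 5.0))
        return f.Spectrum(ppm, y)

    def test_shifts_doublet_to_reference(self):
        spec = self._doublet(5.26)
        cal = f.calibrate(spec, reference_ppm=5.24, search_window=0.1)
        shift = cal.ppm[0] - spec.ppm[0]
        assert shift == pytest.approx(-0.02, abs=2e-4)

    def test_idempotent(self):
        cal1 = f.calibrate(self._doublet(5.27), 5.24)
        cal2 = f.calibrate(cal1, 5.24)
        assert np.abs(cal2.ppm - cal1.ppm).max() < 1e-9

    def test_intensities_untouched(self):
        spec = self._doublet(5.26)
        cal = f.calibrate(spec, 5.24)
        assert np.array_equal(cal.intensity, spec.intensity)

    def test_flat_spectrum_fails(self):
        ppm = np.linspace(0, 10.2, 2048)
        with pytest.raises(CalibrationError):
            f.calibrate(f.Spectrum(ppm, np.ones(ppm.size)), 5.24)


# ---------------------------------------------------------------------------
# bucket / exclude / normalize


class TestBucketing:
    def test_default_window_gives_490_bins(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        values, centers = f.bucket(spec, 0.20, 10.00, 0.02)
        assert values.size == centers.size == 490

    def test_flat_integrand(self, small_axis):
        c = 3.7
        spec = f.Spectrum(small_axis, np.full(small_axis.size, c))
        values, _ = f.bucket(spec, 0.20, 10.00, 0.02)
        assert np.abs(values - c * 0.02).max() < 1e-12

    def test_bucket_sum_equals_total_integral(self, small_axis):
        rng = np.random.default_rng(5)
        spec = f.Spectrum(small_axis, rng.random(small_axis.size))
        values, _ = f.bucket(spec)
        total = f.integrate_signal(spec, (0.20, 10.00))
        assert values.sum() == pytest.approx(total, rel=1e-9)

    def test_spectrum_must_cover_range(self):
        ppm = np.linspace(1.0, 9.0, 1000)
        with pytest.raises(ValueError):
            f.bucket(f.Spectrum(ppm, np.ones(1000)), 0.20, 10.00, 0.02)

    def test_descending_axis_equivalent(self, small_axis):
        rng = np.random.default_rng(6)
        y = rng.random(small_axis.size)
        up, _ = f.bucket(f.Spectrum(small_axis, y))
        down, _ = f.bucket(f.Spectrum(small_axis[::-1], y[::-1]))
        assert np.allclose(up, down, atol=1e-12)


class TestExclusion:
    def test_default_exclusion_keeps_355_bins(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        values, centers = f.bucket(spec)
        kept, kept_centers = f.exclude_regions(values, centers, [(3.30, 6.00)])
        assert kept.size == 355
        # brute-force oracle: enumerate every bin edge/center independently
        removed = sum(1 for k in range(490)
                      if 3.30 < 0.20 + (k + 0.5) * 0.02 < 6.00)
        assert removed == 135 and kept.size == 490 - removed

    def test_matches_brute_force_membership(self, small_axis):
        rng = np.random.default_rng(7)
        spec = f.Spectrum(small_axis, rng.random(small_axis.size))
        values, centers = f.bucket(spec)
        ranges = [(1.0, 1.5), (3.3, 6.0), (8.8, 9.1)]
        kept, kept_centers = f.exclude_regions(values, centers, ranges)
        oracle = [i for i, c in enumerate(centers)
                  if not any(lo < c < hi for lo, hi in ranges)]
        assert np.array_equal(kept, values[oracle])
        assert np.array_equal(kept_centers, centers[oracle])

    def test_empty_range_list_is_identity(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        values, centers = f.bucket(spec)
        kept, kc = f.exclude_regions(values, centers, [])
        assert np.array_equal(kept, values) and np.array_equal(kc, centers)

    def test_total_exclusion_warns(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        values, centers = f.bucket(spec)
        with pytest.warns(UserWarning):
            kept, _ = f.exclude_regions(values, centers, [(0.0, 10.2)])
        assert kept.size == 0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            exclusion_mask(np.array([1.0, 2.0]), [(6.0, 3.3)])


class TestNormalization:
    def test_simple_arithmetic(self):
        assert np.allclose(f.normalize_total_area(np.array([1.0, 3.0])),
                           [0.25, 0.75])

    def test_failure_on_nonpositive_sum(self):
        with pytest.raises(NormalizationError):
            f.normalize_total_area(np.zeros(4))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=40),
           st.floats(0.1, 100.0))
    def test_scale_invariance_and_idempotence(self, values, scale):
        v = np.asarray(values)
        n1 = f.normalize_total_area(v)
        assert n1.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(f.normalize_total_area(v * scale), n1, atol=1e-12)
        assert np.allclose(f.normalize_total_area(n1), n1, atol=1e-12)


# ---------------------------------------------------------------------------
# integrate_signal / build_bucket_matrix


class TestIntegration:
    def test_rectangle(self):
        ppm = np.linspace(0, 10, 100001)
        y = np.where((ppm >= 2.0) & (ppm <= 2.1), 1.0, 0.0)
        area = f.integrate_signal(f.Spectrum(ppm, y), (1.5, 2.5))
        assert area == pytest.approx(0.1, abs=1e-3)

    def test_additivity_over_disjoint_regions(self, small_axis):
        rng = np.random.default_rng(8)
        spec = f.Spectrum(small_axis, rng.random(small_axis.size))
        whole = f.integrate_signal(spec, (1.0, 3.0))
        parts = (f.integrate_signal(spec, (1.0, 1.7))
                 + f.integrate_signal(spec, (1.7, 3.0)))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_lorentzian_analytic_area(self):
        ppm = np.linspace(0, 10.2, 16384)
        amp, hwhm = 3.0, 0.01
        spec = f.Spectrum(ppm, lorentzian(ppm, 5.0, hwhm, amp))
        area = f.integrate_signal(spec, (4.3, 5.7))
        assert area == pytest.approx(np.pi * amp * hwhm, rel=0.01)

    def test_inverted_region_rejected(self, small_axis):
        spec = f.Spectrum(small_axis, np.ones(small_axis.size))
        with pytest.raises(ValueError):
            f.integrate_signal(spec, (5.0, 4.0))


class TestBucketMatrix:
    def test_matrix_shape_and_row_sums(self, small_axis):
        design = f.CohortDesign(n_subjects_per_group=3, paired=False,
                                noise_sd=0.0, seed=2, axis=small_axis)
        samples = f.simulate_cohort(design)
        matrix = f.build_bucket_matrix([s.spectrum for s in samples])
        assert matrix.values.shape == (6, 355)
        assert np.allclose(matrix.values.sum(axis=1), 1.0, atol=1e-9)
        assert matrix.normalized and matrix.excluded_ranges == ((3.30, 6.00),)

    def test_single_spectrum(self, small_axis):
        spec = f.Spectrum(small_axis, np.abs(np.sin(small_axis)) + 0.1,
                          sample_id="only")
        matrix = f.build_bucket_matrix([spec])
        assert matrix.values.shape[0] == 1 and matrix.sample_ids == ["only"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            f.build_bucket_matrix([])

    def test_mixed_acquisitions_rejected(self, small_axis):
        y = np.ones(small_axis.size)
        specs = [f.Spectrum(small_axis, y, acquisition="cpmg"),
                 f.Spectrum(small_axis, y, acquisition="noesy")]
        with pytest.raises(ValueError):
            f.build_bucket_matrix(specs)

    def test_csv_round_trip(self, tmp_path, small_axis):
        rng = np.random.default_rng(9)
        specs = [f.Spectrum(small_axis, rng.random(small_axis.size) + 0.1,
                            sample_id=f"s{i}") for i in range(3)]
        matrix = f.build_bucket_matrix(specs)
        matrix.to_csv(tmp_path / "m.csv")
        back = f.BucketMatrix.from_csv(tmp_path / "m.csv")
        assert np.allclose(back.values, matrix.values, atol=1e-12)
        assert back.sample_ids == matrix.sample_ids
        assert back.excluded_ranges == matrix.excluded_ranges
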