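"""Preprocessing stages: I/O, averaging, baseline, smoothing, grids, peaks."""

import numpy as np
import pytest

from palmraman import preprocess as prep
from palmraman.preprocess import (
    RamanSpectrum, average_replicates, baseline_correct, crop_band,
    find_reference_peak, interpolate_uniform, read_spectrum_csv, smooth_savgol,
)
from palmraman.synthetic_data import (
    DEFAULT_BASELINE, ZERO_BASELINE, ComponentSpec, default_component_library,
    default_noise_sd, generate_spectrum,
)


def make_spectrum(x, y):
    return RamanSpectrum(np.asarray(x, float), np.asarray(y, float))


class TestRamanSpectrum:
    @pytest.mark.parametrize("shifts,intensities", [
        ([1.0], [2.0]),                       # too short
        ([1.0, 1.0, 2.0], [0, 0, 0]),         # duplicate shift
        ([3.0, 2.0, 1.0], [0, 0, 0]),         # descending
        ([1.0, 2.0, 3.0], [0, np.nan, 0]),    # non-finite
    ])
    def test_invalid_inputs_rejected(self, shifts, intensities):
        with pytest.raises(ValueError):
            RamanSpectrum(np.asarray(shifts), np.asarray(intensities))


class TestReadSpectrumCsv:
    def test_reads_valid_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("raman_shift_cm-1,intensity_au\n1300,5\n1301,6\n1302,7\n")
        s = read_spectrum_csv(p)
        assert len(s) == 3

    def test_text_row_error_names_the_line(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("raman_shift_cm-1,intensity_au\n1300,5\nbroken,row\n")
        with pytest.raises(ValueError, match="line 3"):
            read_spectrum_csv(p)

    def test_descending_file_sorted_with_intensities(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("1302,7\n1301,6\n1300,5\n")
        s = read_spectrum_csv(p)
        np.testing.assert_array_equal(s.shifts, [1300, 1301, 1302])
        np.testing.assert_array_equal(s.intensities, [5, 6, 7])

    def test_duplicate_shifts_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("1300,5\n1300,6\n1302,7\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectrum_csv(p)


class TestAverageReplicates:
    def test_single_spectrum_is_identity(self):
        s = make_spectrum([1, 2, 3], [4, 5, 6])
        out = average_replicates([s])
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_opposite_signals_cancel(self):
        x = np.arange(5.0)
        y = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        out = average_replicates([make_spectrum(x, y), make_spectrum(x, -y)])
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-15)

    def test_constant_spectra_average_to_middle(self):
        x = np.arange(4.0)
        spectra = [make_spectrum(x, np.full(4, v)) for v in (1.0, 2.0, 3.0)]
        out = average_replicates(spectra)
        np.testing.assert_allclose(out.intensities, 2.0)
        assert out.metadata["replicates"] == 3

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([make_spectrum([1, 2, 3], [0, 0, 0]),
                                make_spectrum([1, 2, 4], [0, 0, 0])])


class TestBaselineCorrect:
    def test_reconstruction_is_exact(self):
        lib = default_component_library("sample_B")
        s = generate_spectrum(lib, "ripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd(), seed=4)
        corrected, baseline = baseline_correct(s)
        np.testing.assert_allclose(corrected.intensities + baseline.intensities,
                                   s.intensities, rtol=0, atol=1e-9)

    def test_pure_ramp_fully_removed(self):
        x = np.arange(700.0, 1400.0, 0.5)
        ramp = 0.1 * (x - 700.0)
        corrected, _ = baseline_correct(RamanSpectrum(x, ramp))
        assert np.max(np.abs(corrected.intensities)) < 0.01 * np.ptp(ramp)

    def test_peaks_only_leave_small_baseline(self):
        lib = default_component_library("sample_B")
        s = generate_spectrum(lib, "ripe", ZERO_BASELINE, noise_sd=0.0)
        _, baseline = baseline_correct(s)
        tallest = s.intensities.max()
        assert np.max(np.abs(baseline.intensities)) < 0.05 * tallest

    def test_second_application_nearly_idempotent(self):
        lib = default_component_library("sample_B")
        s = generate_spectrum(lib, "ripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd(), seed=5)
        once, _ = baseline_correct(s)
        twice, _ = baseline_correct(once)
        peak = once.intensities.max()
        assert np.max(np.abs(twice.intensities - once.intensities)) < 0.01 * peak

    def test_invalid_parameters_rejected(self):
        s = make_spectrum([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            baseline_correct(s, lam=-1.0)
        with pytest.raises(ValueError):
            baseline_correct(s, p=1.5)


class TestSmoothSavgol:
    def test_constant_signal_unchanged(self):
        s = make_spectrum(np.arange(30.0), np.full(30, 7.0))
        out = smooth_savgol(s, window=11, order=3)
        np.testing.assert_allclose(out.intensities, 7.0)

    def test_cubic_reproduced_exactly(self):
        x = np.arange(40.0)
        y = 0.5 * x**3 - 2 * x**2 + x - 3
        out = smooth_savgol(make_spectrum(x, y), window=11, order=3)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-9)

    def test_interior_matches_local_polyfit_oracle(self, rng):
        """Each interior smoothed value equals an independent least-squares
        polynomial fitted to its window and evaluated at the point."""
        x = np.arange(60.0)
        y = np.sin(x / 6.0) * 10 + rng.normal(0, 1.0, x.size)
        window, order = 11, 3
        out = smooth_savgol(make_spectrum(x, y), window, order)
        half = window // 2
        for i in range(half, x.size - half):
            xs = x[i - half:i + half + 1]
            ys = y[i - half:i + half + 1]
            coeffs = np.polyfit(xs - x[i], ys, order)
            assert out.intensities[i] == pytest.approx(coeffs[-1], rel=1e-9, abs=1e-9)

    def test_preconditions(self):
        s = make_spectrum(np.arange(20.0), np.zeros(20))
        with pytest.raises(ValueError):
            smooth_savgol(s, window=10, order=3)   # even window
        with pytest.raises(ValueError):
            smooth_savgol(s, window=3, order=3)    # window <= order
        with pytest.raises(ValueError):
            smooth_savgol(s, window=21, order=3)   # window >= length
        nonuniform = make_spectrum([0, 1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12],
                                   np.zeros(12))
        with pytest.raises(ValueError):
            smooth_savgol(nonuniform, window=5, order=2)


class TestInterpolateUniform:
    def test_already_uniform_unchanged(self):
        x = np.arange(1240.0, 1361.0, 0.5)
        y = np.sin(x)
        out = interpolate_uniform(make_spectrum(x, y), step=0.5)
        np.testing.assert_allclose(out.shifts, x)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-12)

    def test_linear_midpoint(self):
        out = interpolate_uniform(make_spectrum([1300.0, 1302.0], [10.0, 20.0]), step=1.0)
        i = np.where(out.shifts == 1301.0)[0][0]
        assert out.intensities[i] == pytest.approx(15.0)

    def test_band_point_count(self):
        x = np.linspace(1240.0, 1360.0, 777)
        out = interpolate_uniform(make_spectrum(x, np.zeros_like(x)), step=0.5)
        assert len(out) == 241

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError):
            interpolate_uniform(make_spectrum([1300.0, 1301.0], [0, 0]), step=5.0)


class TestCropBand:
    def test_band_bounds_inclusive(self):
        x = np.arange(700.0, 1400.5, 0.5)
        out = crop_band(make_spectrum(x, np.zeros_like(x)), 1240.0, 1360.0)
        assert out.shifts[0] == 1240.0
        assert out.shifts[-1] == 1360.0

    def test_covering_crop_is_identity(self):
        s = make_spectrum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = crop_band(s, 0.0, 10.0)
        np.testing.assert_array_equal(out.shifts, s.shifts)

    def test_empty_crop_rejected(self):
        with pytest.raises(ValueError):
            crop_band(make_spectrum([1.0, 2.0, 3.0], [0, 0, 0]), 5.0, 6.0)


class TestFindReferencePeak:
    def test_chlorophyll_744_located_on_raw_spectrum(self):
        lib = default_component_library("full_range")
        s = generate_spectrum(lib, "under_ripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd("full_range"), seed=3)
        res = find_reference_peak(s, 744.0, window=10.0)
        assert res is not None
        position, intensity = res
        assert abs(position - 744.0) <= 3.0
        assert intensity > 0

    def test_missing_band_reported_absent(self):
        lib = default_component_library("full_range")
        s = generate_spectrum(lib, "over_ripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd("full_range"), seed=3)
        # the 915 cm^-1 chlorophyll band has zero amplitude when over-ripe;
        # baseline-correct first so the sloping background does not fake peaks
        corrected, _ = baseline_correct(s)
        assert find_reference_peak(corrected, 915.0, window=6.0) is None

    def test_single_gaussian_returns_amplitude(self):
        comp = ComponentSpec("X", "test", {"ripe": 986.0}, {"ripe": 55.0},
                             center_jitter_sd=0.0, amplitude_cv=0.0, width_cv=0.0)
        s = generate_spectrum([comp], "ripe", ZERO_BASELINE, noise_sd=0.0)
        position, intensity = find_reference_peak(s, 986.0, window=10.0)
        assert position == pytest.approx(986.0)
        assert intensity == pytest.approx(55.0, rel=1e-6)

    def test_reference_outside_grid_rejected(self):
        s = make_spectrum(np.arange(700.0, 800.0), np.zeros(100))
        with pytest.raises(ValueError):
            find_reference_peak(s, 1325.0, window=10.0)
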