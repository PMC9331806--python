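"""Gaussian-mixture band deconvolution: recovery, pruning, fit statistics."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from palmraman import preprocess as prep
from palmraman.deconvolution import (
    AREA_FACTOR, DEFAULT_INIT_CENTERS, FWHM_FACTOR, GaussianPeak,
    INIT_CENTERS_BY_MODE, deconvolve_spectrum, fit_gaussian_mixture,
    peak_table, prune_insignificant, reduced_chi_squared,
)
from palmraman.synthetic_data import (
    DEFAULT_BASELINE, ZERO_BASELINE, CohortSpec, default_component_library,
    default_noise_sd, generate_cohort, generate_spectrum,
)


def band_from_components(components, noise_sd=0.0, seed=0):
    """Noisy band spectrum on the 1240-1360 grid from (A, mu, sigma) triples."""
    x = np.arange(1240.0, 1360.5, 0.5)
    y = np.zeros_like(x)
    for a, mu, sg in components:
        y += a * np.exp(-0.5 * ((x - mu) / sg) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, x.size)
    return prep.RamanSpectrum(x, y)


class TestGaussianPeakClosedForms:
    @pytest.mark.parametrize("amplitude,sigma", [(100.0, 5.0), (1.0, 1.5), (317.2, 9.3)])
    def test_fwhm_and_area_relations(self, amplitude, sigma):
        p = GaussianPeak("P1", "x", 1300.0, amplitude, sigma)
        assert p.fwhm / p.sigma == pytest.approx(2.3548200450309493, abs=1e-9)
        assert p.area / (p.amplitude * p.sigma) == pytest.approx(2.5066282746310002,
                                                                 abs=1e-9)

    def test_reference_values(self):
        p = GaussianPeak("P4", "lipid", 1306.0, 100.0, 5.0)
        assert p.fwhm == pytest.approx(11.7741, abs=1e-4)
        assert p.area == pytest.approx(1253.31, abs=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaussianPeak("P1", "x", 1300.0, -1.0, 5.0)
        with pytest.raises(ValueError):
            GaussianPeak("P1", "x", 1300.0, 1.0, 0.0)


class TestFitGaussianMixture:
    def test_single_gaussian_exact_recovery(self):
        band = band_from_components([(100.0, 1306.0, 5.0)])
        fit = fit_gaussian_mixture(band)
        p4 = fit.peak("P4")
        assert p4.amplitude == pytest.approx(100.0, rel=1e-6)
        assert p4.center == pytest.approx(1306.0, rel=1e-6)
        assert p4.sigma == pytest.approx(5.0, rel=1e-6)
        others = [p.amplitude for p in fit.peaks if p.label != "P4"]
        assert max(others) < 1e-4

    def test_two_overlapping_gaussians_vs_multistart_oracle(self):
        """The windowed 8-component fit agrees with an independent two-component
        multi-start curve_fit oracle on a heavily overlapped pair."""
        truth = [(50.0, 1318.0, 5.0), (150.0, 1325.0, 5.0)]
        band = band_from_components(truth)
        fit = fit_gaussian_mixture(band)
        got = sorted(((p.amplitude, p.center, p.sigma) for p in fit.peaks
                      if p.amplitude > 1.0), key=lambda t: t[1])

        def two_gauss(x, a1, m1, s1, a2, m2, s2):
            return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
                    + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))

        best = None
        for m1 in (1315.0, 1318.0, 1320.0):
            for m2 in (1323.0, 1325.0, 1328.0):
                try:
                    popt, _ = curve_fit(two_gauss, band.shifts, band.intensities,
                                        p0=[80, m1, 4, 80, m2, 4], maxfev=20000)
                except RuntimeError:
                    continue
                rss = np.sum((two_gauss(band.shifts, *popt) - band.intensities) ** 2)
                if best is None or rss < best[0]:
                    best = (rss, popt)
        oracle = sorted([tuple(best[1][:3]), tuple(best[1][3:])], key=lambda t: t[1])
        for (a, m, s), (oa, om, os_) in zip(got, oracle):
            assert a == pytest.approx(oa, rel=1e-3)
            assert m == pytest.approx(om, rel=1e-3)
            assert s == pytest.approx(abs(os_), rel=1e-3)
        for (a, m, s), (ta, tm, ts) in zip(got, truth):
            assert a == pytest.approx(ta, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noiseless_model_class_exact_recovery(self, seed):
        """Any noiseless spectrum inside the model class is recovered to 1e-6
        relative (amplitudes, centers, sigmas of expressed components)."""
        rng = np.random.default_rng(seed)
        inits = INIT_CENTERS_BY_MODE["sample_B"]
        truth = []
        for mu0 in inits:
            truth.append((float(rng.uniform(50, 500)),
                          float(mu0 + rng.uniform(-2, 2)),
                          float(rng.uniform(3.5, 6.5))))
        band = band_from_components(truth)
        fit = fit_gaussian_mixture(band, init_centers=inits)
        got = sorted(fit.peaks, key=lambda p: p.center)
        for p, (ta, tm, ts) in zip(got, sorted(truth, key=lambda t: t[1])):
            assert p.amplitude == pytest.approx(ta, rel=1e-6)
            assert p.center == pytest.approx(tm, rel=1e-6)
            assert p.sigma == pytest.approx(ts, rel=1e-6)

    def test_model_plus_residuals_reconstructs_band(self):
        lib = default_component_library("sample_B")
        s = generate_spectrum(lib, "ripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd(), seed=6)
        band = prep.preprocess_spectrum(s, smooth=False)
        fit = fit_gaussian_mixture(band, init_centers=INIT_CENTERS_BY_MODE["sample_B"])
        np.testing.assert_allclose(fit.model() + fit.residuals, band.intensities,
                                   atol=1e-9)

    def test_band_too_short_rejected(self):
        x = np.arange(1240.0, 1270.0, 0.5)
        with pytest.raises(ValueError, match="points"):
            fit_gaussian_mixture(prep.RamanSpectrum(x, np.zeros_like(x)))

    def test_noise_robust_recovery_across_replicates(self):
        """At default noise the expressed proportional bands are recovered with
        centers within 2 cm^-1 and amplitudes within 10% in >= 90% of fruit."""
        ds = generate_cohort(CohortSpec(
            counts={"under_ripe": 4, "ripe": 4, "over_ripe": 4}, seed=9))
        noise = default_noise_sd()
        checks = []
        for i, (s, lab) in enumerate(ds.samples):
            band = prep.preprocess_spectrum(s, smooth=False)
            fit = deconvolve_spectrum(band, noise_sd=noise, mode="sample_B", seed=i)
            truth = s.metadata["true_components"]
            for label in ("P1", "P2", "P3", "P4", "P5", "P8"):
                ta, tm, ts = truth[label]
                p = fit.peak(label)
                checks.append(p.present
                              and abs(p.center - tm) <= 2.0
                              and abs(p.amplitude - ta) <= 0.10 * ta)
        assert np.mean(checks) >= 0.90


class TestPruneInsignificant:
    def test_zero_amplitude_component_pruned(self):
        band = band_from_components([(100.0, 1306.0, 5.0), (80.0, 1281.0, 5.0)])
        fit = fit_gaussian_mixture(band)
        pruned = prune_insignificant(fit, band)
        assert pruned.peak("P4").present and pruned.peak("P3").present
        for label in ("P1", "P2", "P5", "P6", "P7", "P8"):
            assert not pruned.peak(label).present
        assert pruned.peak("P4").amplitude == pytest.approx(100.0, rel=1e-6)

    def test_sample_a_unripe_guanine_cytosine_pruned(self):
        lib = default_component_library("sample_A")
        s = generate_spectrum(lib, "unripe", DEFAULT_BASELINE,
                              noise_sd=default_noise_sd("sample_A"), seed=1)
        band = prep.preprocess_spectrum(s, smooth=False)
        fit = deconvolve_spectrum(band, noise_sd=default_noise_sd("sample_A"),
                                  mode="sample_A", seed=1)
        assert not fit.peak("P5").present

    def test_noiseless_full_component_spectrum_keeps_everything(self):
        amps = (343.0, 175.0, 686.0, 233.0, 284.0, 160.0, 174.0, 334.0)
        truth = [(a, mu, 5.0) for a, mu in zip(amps, INIT_CENTERS_BY_MODE["sample_B"])]
        band = band_from_components(truth)
        fit = fit_gaussian_mixture(band, init_centers=INIT_CENTERS_BY_MODE["sample_B"])
        pruned = prune_insignificant(fit, band)
        assert all(p.present for p in pruned.peaks)

    def test_all_pruned_flags_degenerate(self):
        x = np.arange(1240.0, 1360.5, 0.5)
        band = prep.RamanSpectrum(x, np.random.default_rng(0).normal(0, 1.0, x.size))
        fit = fit_gaussian_mixture(band, noise_sd=1.0)
        pruned = prune_insignificant(fit, band, noise_sd=1e9)
        assert pruned.degenerate
        assert not any(p.present for p in pruned.peaks)


class TestReducedChiSquared:
    def test_perfect_model_gives_zero(self):
        y = np.arange(100.0)
        assert reduced_chi_squared(y, y, 5) == 0.0

    def test_constant_residual_scale(self):
        n, k, sd = 200, 24, 3.0
        obs = np.full(n, sd)
        model = np.zeros(n)
        val = reduced_chi_squared(obs, model, k, noise_sd=sd)
        assert val == pytest.approx(n / (n - k))

    def test_known_noise_fixture_in_expected_range(self):
        lib = default_component_library("sample_B")
        noise = default_noise_sd()
        s = generate_spectrum(lib, "ripe", ZERO_BASELINE, noise_sd=noise, seed=11)
        band = prep.crop_band(s, 1240.0, 1360.0)
        fit = fit_gaussian_mixture(band, init_centers=INIT_CENTERS_BY_MODE["sample_B"],
                                   noise_sd=noise)
        assert 0.5 <= fit.reduced_chi_squared <= 2.0

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(ValueError):
            reduced_chi_squared(np.zeros(5), np.zeros(5), 5)


class TestPeakTable:
    def test_closed_form_columns(self):
        band = band_from_components([(100.0, 1306.0, 5.0)])
        fit = prune_insignificant(fit_gaussian_mixture(band), band)
        table = peak_table(fit, sample_id="s0", label="ripe")
        row = table[table["peak"] == "P4"].iloc[0]
        assert row["fwhm_cm-1"] == pytest.approx(11.7741, abs=1e-3)
        assert row["area"] == pytest.approx(1253.31, rel=1e-4)
        assert row["present"]

    def test_pruned_rows_have_blank_cells(self):
        band = band_from_components([(100.0, 1306.0, 5.0)])
        fit = prune_insignificant(fit_gaussian_mixture(band), band)
        table = peak_table(fit)
        absent = table[~table["present"]]
        assert len(absent) == 7
        assert absent["intensity_au"].isna().all()

    def test_default_ripe_amide_iii_center_in_printed_range(self, default_run):
        import pandas as pd
        _, out = default_run
        peaks = pd.read_csv(out / "peaks.csv")
        p1 = peaks[(peaks["peak"] == "P1") & (peaks["class"] == "ripe")
                   & peaks["present"]]
        assert ((p1["center_cm-1"] >= 1240) & (p1["center_cm-1"] <= 1250)).all()
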