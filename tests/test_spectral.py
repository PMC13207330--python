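"""Welch estimation, aperiodic/periodic decomposition, i-APF rules, band
powers and coherence."""

import numpy as np
import pytest

from neuroloop.signal_gen import (
    GaussianPeak,
    Montage,
    SpectralModel,
    SyntheticRecording,
    evaluate_model_psd,
    synthesize_recording,
)
from neuroloop.spectral import (
    DEFAULT_BANDS,
    BandDefinition,
    FitError,
    NoAlphaRhythmError,
    PeakSet,
    PowerSpectrum,
    alpha_peak_frequency,
    band_power,
    coherence,
    compute_psd,
    extract_peaks,
    fit_aperiodic,
    flatten_spectrum,
    iapf_center_of_gravity,
    iapf_top3_average,
    power_ratio,
    triple_channel_coherence,
)


def make_recording(samples: np.ndarray, fs: float, labels) -> SyntheticRecording:
    montage = Montage(channel_labels=tuple(labels), sampling_rate=fs)
    return SyntheticRecording(
        montage=montage, duration=samples.shape[1] / fs, samples=samples,
        truth={ch: SpectralModel() for ch in labels}, seed=0,
    )


def exact_spectrum(model: SpectralModel, df: float = 0.5,
                   fmax: float = 60.0) -> PowerSpectrum:
    """Noiseless model spectrum directly on a grid (no estimation)."""
    freqs = np.arange(df, fmax + df / 2, df)
    power = evaluate_model_psd(model, freqs)[None, :]
    return PowerSpectrum(freqs=freqs, power=power, channels=("X",),
                         window_length=1 / df, overlap=0.5)


class TestComputePsd:
    def test_pure_tone_peaks_at_its_bin(self):
        fs = 256.0
        t = np.arange(0, 20.0, 1 / fs)
        samples = np.sin(2 * np.pi * 10.0 * t)[None, :]
        spec = compute_psd(make_recording(samples, fs, ["X"]), window_length=2.0)
        assert spec.freqs[np.argmax(spec.power[0])] == pytest.approx(10.0)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal((1, 256 * 240))
        spec = compute_psd(make_recording(samples, 256.0, ["X"]))
        sel = (spec.freqs > 1) & (spec.freqs < 120)
        p = spec.power[0][sel]
        assert np.std(p) / np.mean(p) < 0.15

    def test_frequency_resolution_is_inverse_window(self, alpha_recording):
        spec = compute_psd(alpha_recording, window_length=2.0)
        assert np.diff(spec.freqs)[0] == pytest.approx(0.5)

    def test_overlap_validation(self, alpha_recording):
        with pytest.raises(ValueError):
            compute_psd(alpha_recording, overlap=0.95)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(3)
        fs = 256.0
        samples = rng.standard_normal((1, int(fs) * 120))
        spec = compute_psd(make_recording(samples, fs, ["X"]))
        total = np.trapezoid(spec.power[0], spec.freqs)
        assert total == pytest.approx(np.var(samples), rel=0.05)


class TestAperiodicFit:
    def test_exact_one_over_f(self):
        model = SpectralModel(aperiodic_offset=3.0, aperiodic_exponent=1.0)
        fit = fit_aperiodic(exact_spectrum(model), fit_range=(1.0, 40.0))
        assert fit.exponent == pytest.approx(1.0, abs=1e-3)
        assert fit.offset == pytest.approx(3.0, rel=1e-2)
        assert fit.goodness > 0.999

    def test_flat_spectrum_gives_zero_exponent(self):
        model = SpectralModel(aperiodic_offset=2.0, aperiodic_exponent=0.0)
        fit = fit_aperiodic(exact_spectrum(model))
        assert fit.exponent == pytest.approx(0.0, abs=1e-3)

    def test_recovers_exponent_under_peak(self, alpha_recording):
        fit = fit_aperiodic(compute_psd(alpha_recording))
        assert fit.exponent == pytest.approx(1.5, abs=0.15)

    def test_too_few_bins_raises(self):
        model = SpectralModel(aperiodic_offset=1.0, aperiodic_exponent=1.0)
        spec = exact_spectrum(model, df=2.0, fmax=10.0)
        with pytest.raises(FitError):
            fit_aperiodic(spec, fit_range=(1.0, 10.0))

    def test_flattening_removes_aperiodic_trend(self):
        """After subtracting the fit from an exact model spectrum the
        remainder is the peak alone — no residual 1/f trend."""
        model = SpectralModel(aperiodic_offset=5.0, aperiodic_exponent=1.2,
                              peaks=(GaussianPeak(10.0, 2.0, 1.0),))
        spec = exact_spectrum(model)
        fit = fit_aperiodic(spec)
        flat = flatten_spectrum(spec, fit)
        peak_only = evaluate_model_psd(
            SpectralModel(peaks=model.peaks), spec.freqs)
        off_peak = np.abs(spec.freqs - 10.0) > 4.0
        assert np.max(np.abs(flat - peak_only)[off_peak]) < 0.05


class TestExtractPeaks:
    def test_zero_flattened_gives_empty_peakset(self):
        model = SpectralModel(aperiodic_offset=4.0, aperiodic_exponent=1.0)
        spec = exact_spectrum(model)
        fit = fit_aperiodic(spec)
        ps = extract_peaks(spec, fit)
        assert ps.peaks == ()

    def test_single_peak_recovery(self, alpha_recording):
        spec = compute_psd(alpha_recording)
        fit = fit_aperiodic(spec)
        ps = extract_peaks(spec, fit)
        apk = alpha_peak_frequency(ps)
        assert apk == pytest.approx(10.0, abs=0.25)

    def test_two_separated_peaks_matched_by_nearest_center(self, o1_montage):
        model = SpectralModel(
            noise_floor=0.05, aperiodic_offset=10.0, aperiodic_exponent=1.0,
            peaks=(GaussianPeak(6.0, 3.0, 0.8), GaussianPeak(10.0, 2.5, 0.8)),
        )
        rec = synthesize_recording({"O1": model}, o1_montage, 120.0, seed=21)
        spec = compute_psd(rec)
        fit = fit_aperiodic(spec)
        found = extract_peaks(spec, fit, max_peaks=3).peaks
        for target in (6.0, 10.0):
            nearest = min(found, key=lambda p: abs(p.center_freq - target))
            assert nearest.center_freq == pytest.approx(target, abs=0.25)


class TestIapfCenterOfGravity:
    def grid_peakset(self, weights, freqs):
        return PeakSet(peaks=(), channel="O1", freqs=np.asarray(freqs),
                       flattened=np.asarray(weights), fit_range=(1.0, 40.0))

    def test_symmetric_peak_centered(self):
        f = np.arange(7.0, 13.01, 0.5)
        w = np.exp(-((f - 10.0) ** 2) / 2.0)
        est = iapf_center_of_gravity(self.grid_peakset(w, f))
        assert est.value == pytest.approx(10.0)

    def test_equal_twin_peaks_average(self):
        f = np.arange(7.0, 13.01, 0.5)
        w = np.exp(-((f - 9.0) ** 2) / 0.08) + np.exp(-((f - 11.0) ** 2) / 0.08)
        est = iapf_center_of_gravity(self.grid_peakset(w, f))
        assert est.value == pytest.approx(10.0, abs=1e-6)

    def test_amplitude_weighted_two_bins(self):
        # idealized two-bin reduction: (3*9 + 1*11) / 4 = 9.5
        f = np.array([9.0, 11.0])
        w = np.array([3.0, 1.0])
        est = iapf_center_of_gravity(self.grid_peakset(w, f), band=(8.0, 12.0))
        assert est.value == pytest.approx(9.5)

    def test_brute_force_summation_oracle(self):
        """Full-grid CoG equals a hand-rolled sum over band bins."""
        rng = np.random.default_rng(5)
        f = np.arange(1.0, 40.0, 0.5)
        w = rng.uniform(0.0, 1.0, size=f.size)
        ps = self.grid_peakset(w, f)
        est = iapf_center_of_gravity(ps, band=(7.0, 13.0))
        num = den = 0.0
        for fi, wi in zip(f, w):
            if 7.0 <= fi <= 13.0:
                num += fi * wi
                den += wi
        assert est.value == pytest.approx(num / den)

    def test_no_alpha_power_raises(self):
        f = np.arange(1.0, 40.0, 0.5)
        ps = self.grid_peakset(np.zeros_like(f), f)
        with pytest.raises(NoAlphaRhythmError):
            iapf_center_of_gravity(ps)

    def test_prior_window_pulls_toward_prior_mean(self):
        f = np.arange(7.0, 13.01, 0.1)
        w = np.ones_like(f)  # flat: unweighted CoG sits at band center 10
        plain = iapf_center_of_gravity(self.grid_peakset(w, f)).value
        with_prior = iapf_center_of_gravity(
            self.grid_peakset(w, f), prior=(9.2, 1.2)).value
        assert plain == pytest.approx(10.0)
        assert with_prior < plain


class TestIapfTop3:
    def test_all_nodes_equal(self):
        freqs = {ch: 10.0 for ch in ("O1", "O2", "Oz", "P3", "P4", "Pz")}
        assert iapf_top3_average(freqs).value == pytest.approx(10.0)

    def test_three_highest_of_six(self):
        freqs = dict(zip(("O1", "O2", "Oz", "P3", "P4", "Pz"),
                         (9.5, 9.8, 10.1, 8.0, 8.2, 8.4)))
        est = iapf_top3_average(freqs)
        assert est.value == pytest.approx((10.1 + 9.8 + 9.5) / 3)
        assert set(est.contributing_channels) == {"Oz", "O2", "O1"}

    def test_exactly_three_nodes(self):
        est = iapf_top3_average({"O1": 9.0, "O2": 10.0, "Pz": 11.0})
        assert est.value == pytest.approx(10.0)

    def test_fewer_than_three_advises_fallback(self):
        with pytest.raises(ValueError, match="center-of-gravity"):
            iapf_top3_average({"O1": 9.0, "O2": 10.0})

    def test_non_posterior_channels_ignored(self):
        freqs = {"O1": 9.0, "O2": 10.0, "Pz": 11.0, "Fp1": 13.0}
        assert iapf_top3_average(freqs).value == pytest.approx(10.0)


class TestBandPowerAndRatio:
    def test_zero_spectrum(self):
        f = np.arange(1.0, 40.0, 0.5)
        spec = PowerSpectrum(f, np.zeros((1, f.size)), ("X",), 2.0, 0.5)
        assert band_power(spec, DEFAULT_BANDS["Alpha1"]) == 0.0

    def test_unit_density_integrates_to_band_width(self):
        f = np.arange(1.0, 40.0, 0.5)
        spec = PowerSpectrum(f, np.ones((1, f.size)), ("X",), 2.0, 0.5)
        band = BandDefinition("custom", 8.0, 12.0)
        assert band_power(spec, band) == pytest.approx(4.0)

    def test_gaussian_peak_area_closed_form(self, alpha_recording):
        spec = compute_psd(alpha_recording)
        fit = fit_aperiodic(spec)
        flat = flatten_spectrum(spec, fit)
        flat_spec = PowerSpectrum(spec.freqs, flat[None, :], ("O1",), 2.0, 0.5)
        band = BandDefinition("wide_alpha", 6.0, 14.0)
        # analytic area of the generating peak: a * sigma * sqrt(2*pi)
        expected = 2.0 * 1.0 * np.sqrt(2 * np.pi)
        assert band_power(flat_spec, band) == pytest.approx(expected, rel=0.15)

    def test_ratio_basics(self):
        f = np.arange(1.0, 40.0, 0.5)
        p = np.ones((1, f.size))
        p[0, (f >= 4) & (f <= 8)] = 2.0   # theta density 2
        p[0, (f >= 8) & (f <= 13)] = 4.0  # alpha density 4
        spec = PowerSpectrum(f, p, ("X",), 2.0, 0.5)
        theta = BandDefinition("t", 4.5, 7.5)
        alpha = BandDefinition("a", 8.5, 11.5)
        assert power_ratio(spec, theta, theta) == pytest.approx(1.0)
        assert power_ratio(spec, theta, alpha) == pytest.approx(0.5)

    def test_theta_alpha_ratio_separates_mci_from_healthy(self):
        """Theta-shifted (MCI-like) spectrum has a strictly larger
        Theta/Alpha ratio than a healthy one — the controller's y signal
        discriminates the conditions."""
        healthy = SpectralModel(
            aperiodic_offset=10.0, aperiodic_exponent=1.0,
            peaks=(GaussianPeak(6.0, 0.4, 1.2), GaussianPeak(10.3, 2.5, 1.0)))
        mci = SpectralModel(
            aperiodic_offset=10.0, aperiodic_exponent=1.5,
            peaks=(GaussianPeak(6.0, 1.5, 1.2), GaussianPeak(9.0, 1.0, 1.0)))
        theta = DEFAULT_BANDS["Theta"]
        alpha = DEFAULT_BANDS["Mu"]
        ratios = {}
        for name, model in (("healthy", healthy), ("mci", mci)):
            spec = exact_spectrum(model)
            ratios[name] = band_power(spec, theta) / band_power(spec, alpha)
        assert ratios["mci"] > ratios["healthy"]


class TestCoherence:
    fs = 256.0

    def test_identical_copies_fully_coherent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(self.fs) * 60)
        rec = make_recording(np.vstack([x, x]), self.fs, ["A", "B"])
        band = DEFAULT_BANDS["Alpha1"]
        assert coherence(rec, "A", "B", band) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        samples = rng.standard_normal((2, int(self.fs) * 240))
        rec = make_recording(samples, self.fs, ["A", "B"])
        assert coherence(rec, "A", "B", DEFAULT_BANDS["Alpha1"]) < 0.2

    def test_shared_source_intermediate(self):
        rng = np.random.default_rng(3)
        n = int(self.fs) * 120
        t = np.arange(n) / self.fs
        shared = np.sin(2 * np.pi * 10.0 * t)
        a = shared + rng.standard_normal(n)
        b = shared + rng.standard_normal(n)
        rec = make_recording(np.vstack([a, b]), self.fs, ["A", "B"])
        c = coherence(rec, "A", "B", DEFAULT_BANDS["Alpha1"])
        assert 0.2 < c < 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        samples = rng.standard_normal((2, int(self.fs) * 60))
        samples[1] += 0.5 * samples[0]
        rec = make_recording(samples, self.fs, ["A", "B"])
        band = DEFAULT_BANDS["Theta"]
        cab = coherence(rec, "A", "B", band)
        cba = coherence(rec, "B", "A", band)
        assert cab == pytest.approx(cba)
        assert 0.0 <= cab <= 1.0

    def test_same_channel_rejected(self, alpha_recording):
        with pytest.raises(ValueError):
            coherence(alpha_recording, "O1", "O1", DEFAULT_BANDS["Alpha1"])

    def test_triple_channel_mean_of_pairs(self):
        rng = np.random.default_rng(5)
        n = int(self.fs) * 60
        samples = rng.standard_normal((3, n))
        rec = make_recording(samples, self.fs, ["C3", "C4", "Cz"])
        band = DEFAULT_BANDS["Mu"]
        tri = triple_channel_coherence(rec, band)
        pairs = [coherence(rec, a, b, band)
                 for a, b in (("C3", "C4"), ("C3", "Cz"), ("C4", "Cz"))]
        assert tri == pytest.approx(np.mean(pairs))


def test_spectrum_and_fit_serialization(tmp_path, alpha_recording):
    import json

    import pandas as pd

    from neuroloop.spectral import write_fit_json, write_spectrum_csv

    spec = compute_psd(alpha_recording)
    csv_path = write_spectrum_csv(spec, tmp_path / "psd.csv")
    df = pd.read_csv(csv_path)
    assert list(df.columns) == ["freq_hz", "O1"]
    assert np.allclose(df["O1"], spec.power[0])

    fit = fit_aperiodic(spec)
    json_path = write_fit_json({"O1": fit}, tmp_path / "fits.json")
    payload = json.loads(json_path.read_text())
    assert payload["O1"]["exponent"] == pytest.approx(fit.exponent)


def test_iapf_methods_agree_on_single_peak_subject(o1_montage):
    """Both i-APF rules see the same synthetic peak (within 0.3 Hz)."""
    labels = ("O1", "O2", "Pz")
    montage = Montage(channel_labels=labels, sampling_rate=256.0)
    model = SpectralModel(noise_floor=0.05, aperiodic_offset=10.0,
                          aperiodic_exponent=1.5,
                          peaks=(GaussianPeak(9.6, 2.0, 1.0),))
    rec = synthesize_recording({ch: model for ch in labels}, montage, 120.0, seed=8)
    spec = compute_psd(rec)
    cog_vals, peak_freqs = [], {}
    for ch in labels:
        fit = fit_aperiodic(spec, channel=ch)
        ps = extract_peaks(spec, fit, channel=ch)
        cog_vals.append(iapf_center_of_gravity(ps).value)
        peak_freqs[ch] = alpha_peak_frequency(ps)
    cog = np.mean(cog_vals)
    top3 = iapf_top3_average(peak_freqs).value
    assert abs(cog - top3) < 0.3
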