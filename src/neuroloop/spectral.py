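"""Spectral measurement layer: Welch PSDs, aperiodic (1/f) fits, peak
extraction, i-APF estimators, band powers, power ratios and coherence.

The aperiodic component is removed before any alpha-peak statistic so that
i-APF estimates are "pure" — unbiased by the 1/f background that is elevated
in MCI. Two i-APF rules are provided: the center-of-gravity of the flattened
alpha band, and the mean of the three highest per-node alpha peak frequencies
over the posterior nodes O1/O2/Oz/P3/P4/Pz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.signal

from .signal_gen import (
    IAPF_NODES,
    GaussianPeak,
    Montage,
    SpectralModel,
    SyntheticRecording,
)

logger = logging.getLogger(__name__)

DEFAULT_FIT_RANGE = (1.0, 40.0)   # Hz, aperiodic fit support
DEFAULT_ALPHA_BAND = (7.0, 13.0)  # Hz, alpha search band


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")


#: Clinical qEEG band scheme. Band names are unique within the scheme; the Mu
#: band overlaps alpha by design (sensorimotor rhythm at C3/C4/Cz).
DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("Delta", 1.0, 4.0),
        BandDefinition("Theta", 4.0, 8.0),
        BandDefinition("Alpha1", 8.0, 10.0),
        BandDefinition("Alpha2", 10.0, 12.0),
        BandDefinition("Beta1", 12.0, 20.0),
        BandDefinition("Beta2", 20.0, 30.0),
        BandDefinition("Gamma", 30.0, 40.0),
        BandDefinition("Mu", 8.0, 13.0),
    )
}

#: High-precision alpha training sub-band for the 76+ protocol (Hz).
PRECISION_ALPHA_BAND = (9.78, 10.25)


@dataclass
class PowerSpectrum:
    """Welch power spectral density per channel (µV²/Hz)."""

    freqs: np.ndarray                 # strictly increasing Hz grid
    power: np.ndarray                 # (n_channels, n_freqs), >= 0
    channels: tuple[str, ...]
    window_length: float              # s
    overlap: float                    # fraction

    def channel_power(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectrum") from None
        return self.power[idx]


def compute_psd(
    recording: SyntheticRecording,
    window_length: float = 2.0,
    overlap: float = 0.5,
) -> PowerSpectrum:
    """Welch PSD with Hann windows; frequency resolution = 1/window_length."""
    if not (0.0 <= overlap <= 0.9):
        raise ValueError(f"overlap must be in [0, 0.9], got {overlap}")
    if recording.duration < window_length:
        raise ValueError("recording shorter than one PSD window")
    fs = recording.montage.sampling_rate
    nperseg = int(round(window_length * fs))
    freqs, power = scipy.signal.welch(
        recording.samples, fs=fs, window="hann",
        nperseg=nperseg, noverlap=int(round(overlap * nperseg)), axis=-1,
    )
    return PowerSpectrum(
        freqs=freqs, power=np.atleast_2d(power),
        channels=recording.montage.channel_labels,
        window_length=window_length, overlap=overlap,
    )


# ---------------------------------------------------------------------------
# Aperiodic (1/f) fitting
# ---------------------------------------------------------------------------

class FitError(RuntimeError):
    """Raised when a spectral fit has too little usable data."""


@dataclass(frozen=True)
class AperiodicFit:
    """Aperiodic model ``L + k * f**(-x)`` fitted over ``fit_range``."""

    noise_floor: float   # L
    offset: float        # k
    exponent: float      # x
    fit_range: tuple[float, float]
    goodness: float      # R² of the masked log-log fit, in [0, 1]

    def evaluate(self, freqs) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        out = np.full_like(f, np.inf)  # aperiodic term undefined at f <= 0
        pos = f > 0
        out[pos] = self.noise_floor + self.offset * f[pos] ** (-self.exponent)
        return out


def _masked_loglog_fit(logf: np.ndarray, logp: np.ndarray,
                       n_iter: int = 8, sd_thresh: float = 2.5):
    """Linear log-log fit with iterative exclusion of bins sitting more than
    ``sd_thresh`` residual SDs above the running fit (peak masking)."""
    mask = np.ones_like(logf, dtype=bool)
    slope = intercept = 0.0
    for _ in range(n_iter):
        if mask.sum() < 10:
            raise FitError("fewer than 10 usable bins after peak masking")
        slope, intercept = np.polyfit(logf[mask], logp[mask], 1)
        resid = logp - (slope * logf + intercept)
        sd = np.std(resid[mask])
        if sd < 1e-12:  # already an exact fit; nothing to mask
            break
        new_mask = resid <= sd_thresh * sd
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if mask.sum() < 10:
        raise FitError("fewer than 10 usable bins after peak masking")
    resid = logp[mask] - (slope * logf[mask] + intercept)
    ss_tot = np.sum((logp[mask] - logp[mask].mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, float(np.clip(r2, 0.0, 1.0)), mask


def _select_channel(spectrum: PowerSpectrum, channel: str | None) -> np.ndarray:
    if channel is None:
        if len(spectrum.channels) != 1:
            raise ValueError("multichannel spectrum: specify a channel label")
        return spectrum.power[0]
    return spectrum.channel_power(channel)


def fit_aperiodic(
    spectrum: PowerSpectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    channel: str | None = None,
) -> AperiodicFit:
    """Fit ``L + k * f**(-x)`` to one channel's PSD.

    A robust log-log linear fit (iteratively masking bins > 2.5 SD above the
    running fit, which removes oscillatory peaks) seeds k and x. The full
    model including a non-negative white-noise floor L is then refined by
    nonlinear least squares in log space on the masked (peak-free) bins, and
    kept only when it improves the fit — model selection between the pure
    1/f and floored variants.
    """
    lo, hi = fit_range
    if lo <= 0:
        raise ValueError("fit_range lower edge must be > 0")
    power = _select_channel(spectrum, channel)
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    f = spectrum.freqs[sel]
    p = power[sel]
    if f.size < 10:
        raise FitError("fewer than 10 bins inside fit_range")
    usable = p > 0
    f, p = f[usable], p[usable]
    if f.size < 10:
        raise FitError("fewer than 10 positive-power bins inside fit_range")
    logf, logp = np.log10(f), np.log10(p)

    slope, intercept, r2_plain, mask = _masked_loglog_fit(logf, logp)
    best = AperiodicFit(0.0, 10.0**intercept, max(-slope, 0.0), fit_range, r2_plain)
    mse_best = float(np.mean((np.log10(np.maximum(best.evaluate(f[mask]), 1e-300))
                              - logp[mask]) ** 2))

    def log_model(freq, log_floor, log_k, x):
        return np.log10(10.0**log_floor + 10.0**log_k * freq ** (-x))

    floor0 = max(float(np.median(p[-max(3, f.size // 10):])) * 0.5, 1e-12)
    try:
        popt, _ = scipy.optimize.curve_fit(
            log_model, f[mask], logp[mask],
            p0=[np.log10(floor0), np.log10(max(best.offset, 1e-12)),
                max(best.exponent, 0.0)],
            bounds=([-30, -30, 0.0], [np.log10(p.max()) + 1, 30, 10.0]),
            maxfev=5000,
        )
    except RuntimeError:
        return best
    # iterate refine + re-mask so the mask is judged against the floored model
    cand = None
    mask2 = mask
    for _ in range(3):
        try:
            popt, _ = scipy.optimize.curve_fit(
                log_model, f[mask2], logp[mask2], p0=list(popt),
                bounds=([-30, -30, 0.0], [np.log10(p.max()) + 1, 30, 10.0]),
                maxfev=5000,
            )
        except RuntimeError:
            break
        cand = AperiodicFit(10.0 ** popt[0], 10.0 ** popt[1], float(popt[2]),
                            fit_range, 0.0)
        resid = logp - np.log10(np.maximum(cand.evaluate(f), 1e-300))
        sd = np.std(resid[mask2])
        new_mask = resid <= 2.5 * sd if sd > 0 else mask2
        if new_mask.sum() < 10 or np.array_equal(new_mask, mask2):
            break
        mask2 = new_mask
    if cand is None:
        return best
    resid = logp - np.log10(np.maximum(cand.evaluate(f), 1e-300))
    mse_cand = float(np.mean(resid[mask2] ** 2))
    if mse_cand < mse_best:
        ss_tot = np.sum((logp[mask2] - logp[mask2].mean()) ** 2)
        r2 = 1.0 - np.sum(resid[mask2] ** 2) / ss_tot if ss_tot > 0 else 1.0
        return AperiodicFit(cand.noise_floor, cand.offset, cand.exponent,
                            fit_range, float(np.clip(r2, 0.0, 1.0)))
    return best


def flatten_spectrum(spectrum: PowerSpectrum, fit: AperiodicFit,
                     channel: str | None = None) -> np.ndarray:
    """Aperiodic-subtracted power, floored at 0 (the 'flattened' spectrum)."""
    power = _select_channel(spectrum, channel)
    return np.clip(power - fit.evaluate(spectrum.freqs), 0.0, None)


# ---------------------------------------------------------------------------
# Periodic peak extraction
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Gaussian peaks fitted to one channel's flattened spectrum."""

    peaks: tuple[GaussianPeak, ...]
    channel: str | None
    freqs: np.ndarray
    flattened: np.ndarray            # aperiodic-subtracted power
    fit_range: tuple[float, float]


def _gauss(f, a, f0, sd):
    return a * np.exp(-((f - f0) ** 2) / (2.0 * sd**2))


def extract_peaks(
    spectrum: PowerSpectrum,
    aperiodic: AperiodicFit,
    max_peaks: int = 4,
    min_amplitude: float = 0.05,
    channel: str | None = None,
    bandwidth_bounds: tuple[float, float] = (0.25, 4.0),
) -> PeakSet:
    """Greedy Gaussian peak fitting on the flattened spectrum.

    The largest residual bin seeds each fit (ties broken toward the lower
    frequency); the fitted Gaussian is subtracted before the next round.
    Peaks with fitted amplitude below ``min_amplitude`` are discarded.

    The working residual is the *unclipped* aperiodic-subtracted power —
    flooring noise at zero would bias fitted centers and amplitudes upward.
    The stored ``flattened`` spectrum (used for center-of-gravity weighting)
    is clipped at zero as a weight function must be.
    """
    lo, hi = aperiodic.fit_range
    power = _select_channel(spectrum, channel)
    flat_full = np.clip(power - aperiodic.evaluate(spectrum.freqs), 0.0, None)
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    f = spectrum.freqs[sel]
    residual = (power - aperiodic.evaluate(spectrum.freqs))[sel].astype(float)

    peaks: list[GaussianPeak] = []
    for _ in range(max_peaks):
        idx = int(np.argmax(residual))  # argmax returns the lowest tied index
        a0 = residual[idx]
        if a0 < min_amplitude:
            break
        f0 = f[idx]
        win = (f >= f0 - 3.0) & (f <= f0 + 3.0)
        try:
            popt, _ = scipy.optimize.curve_fit(
                _gauss, f[win], residual[win],
                p0=[a0, f0, 1.0],
                bounds=([min_amplitude / 2, max(lo, f0 - 2.0), bandwidth_bounds[0]],
                        [np.inf, min(hi, f0 + 2.0), bandwidth_bounds[1]]),
                maxfev=2000,
            )
        except RuntimeError:  # fit failure: mask the bin and move on
            residual[idx] = 0.0
            continue
        a_fit, f_fit, sd_fit = popt
        if a_fit < min_amplitude:
            residual[idx] = 0.0
            continue
        peaks.append(GaussianPeak(float(f_fit), float(a_fit), float(sd_fit)))
        residual = residual - _gauss(f, *popt)

    peaks.sort(key=lambda p: p.center_freq)
    return PeakSet(peaks=tuple(peaks), channel=channel, freqs=spectrum.freqs,
                   flattened=flat_full, fit_range=aperiodic.fit_range)


# ---------------------------------------------------------------------------
# i-APF estimators
# ---------------------------------------------------------------------------

class NoAlphaRhythmError(RuntimeError):
    """No alpha power in the search band — the i-APF is undefined."""


@dataclass(frozen=True)
class IAPFEstimate:
    value: float                     # Hz
    method: str                      # 'center_of_gravity' | 'top3_average'
    band: tuple[float, float]
    contributing_channels: tuple[str, ...] = ()


def iapf_center_of_gravity(
    peakset: PeakSet,
    band: tuple[float, float] = DEFAULT_ALPHA_BAND,
    prior: tuple[float, float] | None = None,
    use_raw: np.ndarray | None = None,
) -> IAPFEstimate:
    """Center-of-gravity i-APF on the flattened ("pure") alpha band.

    Returns ``sum(f * P(f)) / sum(P(f))`` over band bins of the flattened
    spectrum. ``prior=(mu, sd)`` optionally multiplies the weights by a
    Gaussian window (the Bayesian-prior configuration; off by default so the
    estimator stays unbiased). ``use_raw`` substitutes a raw power array for
    the flattened one, for comparison runs.
    """
    lo, hi = band
    weights_src = peakset.flattened if use_raw is None else np.asarray(use_raw)
    sel = (peakset.freqs >= lo) & (peakset.freqs <= hi)
    f = peakset.freqs[sel]
    w = np.clip(weights_src[sel], 0.0, None).astype(float)
    if prior is not None:
        mu, sd = prior
        w = w * np.exp(-((f - mu) ** 2) / (2.0 * sd**2))
    total = w.sum()
    if total <= 0:
        raise NoAlphaRhythmError(f"no alpha power in band ({lo}, {hi}) Hz")
    value = float(np.sum(f * w) / total)
    chans = (peakset.channel,) if peakset.channel else ()
    return IAPFEstimate(value=value, method="center_of_gravity", band=(lo, hi),
                        contributing_channels=chans)


def iapf_top3_average(
    per_channel_peak_freqs: Mapping[str, float],
    nodes: Sequence[str] = IAPF_NODES,
    band: tuple[float, float] = DEFAULT_ALPHA_BAND,
) -> IAPFEstimate:
    """Mean of the 3 highest alpha peak frequencies over the posterior nodes."""
    available = {ch: f for ch, f in per_channel_peak_freqs.items()
                 if ch in nodes and f is not None}
    if len(available) < 3:
        raise ValueError(
            "fewer than 3 posterior nodes with a detected alpha peak; "
            "fall back to the center-of-gravity estimator"
        )
    ranked = sorted(available.items(), key=lambda kv: kv[1], reverse=True)[:3]
    value = float(np.mean([f for _, f in ranked]))
    return IAPFEstimate(value=value, method="top3_average", band=tuple(band),
                        contributing_channels=tuple(ch for ch, _ in ranked))


def alpha_peak_frequency(peakset: PeakSet,
                         band: tuple[float, float] = DEFAULT_ALPHA_BAND) -> float | None:
    """Center frequency of the largest fitted peak inside the alpha band."""
    in_band = [p for p in peakset.peaks if band[0] <= p.center_freq <= band[1]]
    if not in_band:
        return None
    return max(in_band, key=lambda p: p.amplitude).center_freq


# ---------------------------------------------------------------------------
# Band powers, ratios, coherence
# ---------------------------------------------------------------------------

def band_power(spectrum: PowerSpectrum, band: BandDefinition,
               channel: str | None = None) -> float:
    """Trapezoidal integral of the density over the band (µV²)."""
    power = _select_channel(spectrum, channel)
    sel = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band.name} not resolved by the frequency grid")
    return float(np.trapezoid(power[sel], spectrum.freqs[sel]))


def power_ratio(spectrum: PowerSpectrum, numerator: BandDefinition,
                denominator: BandDefinition, channel: str | None = None) -> float:
    """Band-power ratio, e.g. Theta/Alpha — the controller's feedback signal y."""
    den = band_power(spectrum, denominator, channel)
    if den <= 0:
        raise ZeroDivisionError(f"zero power in denominator band {denominator.name}")
    return band_power(spectrum, numerator, channel) / den


def coherence(
    recording: SyntheticRecording,
    ch_a: str,
    ch_b: str,
    band: BandDefinition,
    window_length: float = 2.0,
) -> float:
    """Magnitude-squared coherence averaged over band bins, in [0, 1]."""
    if ch_a == ch_b:
        raise ValueError("coherence requires two distinct channel labels")
    fs = recording.montage.sampling_rate
    nperseg = int(round(window_length * fs))
    f, coh = scipy.signal.coherence(
        recording.channel(ch_a), recording.channel(ch_b),
        fs=fs, window="hann", nperseg=nperseg,
    )
    sel = (f >= band.lo) & (f <= band.hi)
    return float(np.mean(coh[sel]))


def triple_channel_coherence(
    recording: SyntheticRecording,
    band: BandDefinition,
    channels: Sequence[str] = ("C3", "C4", "Cz"),
    window_length: float = 2.0,
) -> float:
    """Mean pairwise coherence over the sensorimotor triple {C3, C4, Cz}."""
    a, b, c = channels
    pairs = [(a, b), (a, c), (b, c)]
    return float(np.mean([
        coherence(recording, x, y, band, window_length) for x, y in pairs
    ]))


# ---------------------------------------------------------------------------
# EDF input (via MNE) and CSV/JSON output
# ---------------------------------------------------------------------------

def load_recording_edf(path: str | Path) -> SyntheticRecording:
    """Read an EDF file into a recording (channels in file order, µV).

    Ground-truth models are attached from a ``.truth.json`` sidecar when one
    exists; otherwise the truth mapping is empty.
    """
    import mne

    from .signal_gen import read_truth_sidecar

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(ch.removeprefix("EEG ").strip() for ch in raw.ch_names)
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    duration = data_uv.shape[1] / fs
    montage = Montage(channel_labels=labels, sampling_rate=fs)
    try:
        truth = read_truth_sidecar(path)
    except FileNotFoundError:
        truth = {}
    return SyntheticRecording(montage=montage, duration=duration,
                              samples=data_uv, truth=truth, seed=-1)


def write_spectrum_csv(spectrum: PowerSpectrum, path: str | Path) -> Path:
    """Write the PSD as a freqs × channels CSV table."""
    import pandas as pd

    df = pd.DataFrame(spectrum.power.T, columns=list(spectrum.channels))
    df.insert(0, "freq_hz", spectrum.freqs)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_fit_json(fits: Mapping[str, AperiodicFit], path: str | Path) -> Path:
    """Write per-channel aperiodic fit metadata as JSON."""
    import json

    payload = {
        ch: {
            "noise_floor": fit.noise_floor,
            "offset": fit.offset,
            "exponent": fit.exponent,
            "fit_range": list(fit.fit_range),
            "goodness": fit.goodness,
        }
        for ch, fit in fits.items()
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
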