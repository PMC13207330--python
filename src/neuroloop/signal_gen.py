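"""Synthetic multichannel EEG and the responsive virtual subject.

The power spectrum of every generated channel follows the additive model

    P(f) = L + k * f**(-x) + sum_i a_i * exp(-(f - f_i)**2 / (2 * sigma_i**2))

with a white-noise floor ``L``, an aperiodic (1/f) component with offset ``k``
and exponent ``x``, and Gaussian oscillatory peaks (theta, alpha, ...).
Time series are produced by spectral shaping of white Gaussian noise, so the
ground-truth model is recoverable by Welch estimation plus aperiodic/periodic
decomposition (the :mod:`neuroloop.spectral` module).

The virtual subject is a small state machine whose alpha peak frequency
(i-APF), alpha/theta amplitudes and aperiodic exponent drift toward normative
targets when rewarded and relax toward their own baseline when not — the
minimal monotone stand-in for a trainee in closed-loop simulations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Standard 19-channel 10–20 montage labels (clinical minimum configuration).
STANDARD_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Posterior/occipital nodes used for i-APF estimation.
IAPF_NODES = ("O1", "O2", "Oz", "P3", "P4", "Pz")

#: MCI-cohort prior on the individual alpha peak frequency (Hz).
IAPF_PRIOR_MEAN = 9.2
IAPF_PRIOR_SD = 1.2

#: Normative alpha center frequency (Hz) used as the default training target.
NORMATIVE_ALPHA_CENTER = 10.25


# ---------------------------------------------------------------------------
# Spectral model (generator input and fitter output)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPeak:
    """One periodic (oscillatory) component of the spectrum."""

    center_freq: float   # Hz
    amplitude: float     # power units (peak height above the aperiodic fit)
    bandwidth_sd: float  # Hz (Gaussian standard deviation)

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError(f"center_freq must be positive, got {self.center_freq}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.bandwidth_sd <= 0:
            raise ValueError(f"bandwidth_sd must be positive, got {self.bandwidth_sd}")


@dataclass(frozen=True)
class SpectralModel:
    """Full spectral model: noise floor + aperiodic 1/f + Gaussian peaks."""

    noise_floor: float = 0.0         # L, power units
    aperiodic_offset: float = 0.0    # k, power units
    aperiodic_exponent: float = 0.0  # x, dimensionless (1/f slope)
    peaks: tuple[GaussianPeak, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.aperiodic_offset < 0:
            raise ValueError("aperiodic_offset must be >= 0")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.center_freq))
        object.__setattr__(self, "peaks", ordered)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpectralModel":
        peaks = tuple(GaussianPeak(**p) for p in d.get("peaks", ()))
        return cls(
            noise_floor=float(d.get("noise_floor", 0.0)),
            aperiodic_offset=float(d.get("aperiodic_offset", 0.0)),
            aperiodic_exponent=float(d.get("aperiodic_exponent", 0.0)),
            peaks=peaks,
        )


def evaluate_model_psd(model: SpectralModel, freqs) -> np.ndarray:
    """Evaluate the model power spectral density on a positive frequency grid.

    Parameters
    ----------
    model
        Spectral model to evaluate.
    freqs
        Frequencies in Hz; all must be strictly positive (the aperiodic term
        ``k * f**(-x)`` is undefined at 0).

    Returns
    -------
    numpy.ndarray
        Power density at each frequency (same units as the model parameters).
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("all frequencies must be strictly positive")
    psd = np.full_like(f, model.noise_floor)
    if model.aperiodic_offset > 0:
        psd = psd + model.aperiodic_offset * f ** (-model.aperiodic_exponent)
    for p in model.peaks:
        psd = psd + p.amplitude * np.exp(-((f - p.center_freq) ** 2) / (2.0 * p.bandwidth_sd**2))
    return psd


# ---------------------------------------------------------------------------
# Montage and recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode montage: channel labels plus a common sampling rate."""

    channel_labels: tuple[str, ...] = STANDARD_1020
    sampling_rate: float = 256.0  # Hz; clinical minimum is 250

    def __post_init__(self) -> None:
        labels = tuple(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate < 250:
            raise ValueError(f"sampling_rate must be >= 250 Hz, got {self.sampling_rate}")
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class SyntheticRecording:
    """Multichannel recording with retained ground-truth spectral models."""

    montage: Montage
    duration: float                      # seconds
    samples: np.ndarray                  # (n_channels, n_samples), µV
    truth: dict[str, SpectralModel]      # per-channel generating model
    seed: int

    def __post_init__(self) -> None:
        n_expected = int(round(self.duration * self.montage.sampling_rate))
        if self.samples.shape != (self.montage.n_channels, n_expected):
            raise ValueError(
                f"samples shape {self.samples.shape} inconsistent with montage "
                f"({self.montage.n_channels} channels x {n_expected} samples)"
            )

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.montage.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None
        return self.samples[idx]


def synthesize_recording(
    models: Mapping[str, SpectralModel],
    montage: Montage,
    duration: float,
    seed: int,
) -> SyntheticRecording:
    """Generate a recording whose Welch PSD matches the per-channel models.

    White Gaussian noise is shaped in the frequency domain: the rFFT of a
    unit-variance noise sequence is multiplied by ``sqrt(P(f) * fs / 2)`` so
    that the one-sided spectral density of the output equals the model PSD.
    The DC bin is zeroed (the model is undefined at 0 Hz and EEG is AC-coupled).

    Deterministic: identical arguments (including ``seed``) give bitwise
    identical samples.
    """
    if duration < 4.0:
        raise ValueError("duration must be >= 4 s (enough Welch segments)")
    missing = [ch for ch in montage.channel_labels if ch not in models]
    if missing:
        raise ValueError(f"no spectral model for channels: {missing}")

    fs = montage.sampling_rate
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    rng = np.random.default_rng(seed)

    samples = np.empty((montage.n_channels, n))
    for i, ch in enumerate(montage.channel_labels):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        gain = np.zeros_like(freqs)
        pos = freqs > 0
        gain[pos] = np.sqrt(evaluate_model_psd(models[ch], freqs[pos]) * fs / 2.0)
        samples[i] = np.fft.irfft(spec * gain, n=n)

    truth = {ch: models[ch] for ch in montage.channel_labels}
    return SyntheticRecording(montage=montage, duration=duration,
                              samples=samples, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# Virtual subject
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualSubjectState:
    """Trainable virtual subject driving the closed loop.

    When an epoch is rewarded the spectral parameters step toward normative
    targets by ``responsiveness * (target - current)``; when not rewarded they
    relax toward the subject's own baseline at one fifth of that rate. The
    i-APF ("neural clock") can accelerate but never beyond ``iapf_ceiling``.
    """

    iapf: float                      # Hz, current alpha peak frequency
    alpha_amplitude: float           # power units, alpha peak height
    theta_amplitude: float           # power units, theta peak height
    aperiodic_exponent: float        # dimensionless 1/f slope
    responsiveness: float            # learning rate per rewarded epoch
    iapf_ceiling: float = NORMATIVE_ALPHA_CENTER

    # normative targets (where training pushes the subject)
    iapf_target: float = NORMATIVE_ALPHA_CENTER
    alpha_target: float = 1.2
    theta_target: float = 0.35
    exponent_target: float = 1.0

    # personal baseline (where the subject relaxes without reward);
    # filled from the initial state when left as None
    iapf_baseline: float | None = None
    alpha_baseline: float | None = None
    theta_baseline: float | None = None
    exponent_baseline: float | None = None

    def __post_init__(self) -> None:
        if not (4.0 < self.iapf < 14.0):
            raise ValueError(f"iapf must lie in (4, 14) Hz, got {self.iapf}")
        if self.responsiveness < 0:
            raise ValueError("responsiveness must be >= 0")
        if self.iapf > self.iapf_ceiling:
            raise ValueError("iapf must not exceed iapf_ceiling")
        for name, current in (
            ("iapf_baseline", self.iapf),
            ("alpha_baseline", self.alpha_amplitude),
            ("theta_baseline", self.theta_amplitude),
            ("exponent_baseline", self.aperiodic_exponent),
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, current)


def subject_step(state: VirtualSubjectState, rewarded: bool) -> VirtualSubjectState:
    """Advance the virtual subject by one feedback epoch (deterministic)."""
    if rewarded:
        r = state.responsiveness
        iapf = state.iapf + r * (state.iapf_target - state.iapf)
        iapf = min(iapf, state.iapf_ceiling)
        alpha = state.alpha_amplitude + r * (state.alpha_target - state.alpha_amplitude)
        theta = state.theta_amplitude + r * (state.theta_target - state.theta_amplitude)
        expo = state.aperiodic_exponent + r * (state.exponent_target - state.aperiodic_exponent)
    else:
        r = state.responsiveness / 5.0
        iapf = state.iapf + r * (state.iapf_baseline - state.iapf)
        alpha = state.alpha_amplitude + r * (state.alpha_baseline - state.alpha_amplitude)
        theta = state.theta_amplitude + r * (state.theta_baseline - state.theta_amplitude)
        expo = state.aperiodic_exponent + r * (state.exponent_baseline - state.aperiodic_exponent)
    return replace(state, iapf=iapf, alpha_amplitude=alpha,
                   theta_amplitude=theta, aperiodic_exponent=expo)


def draw_mci_subject(
    seed: int,
    responsiveness: float = 0.002,
    iapf_bounds: tuple[float, float] = (7.0, 12.0),
) -> VirtualSubjectState:
    """Draw an MCI-like virtual subject from the cohort prior.

    The i-APF is drawn from Normal(9.2, 1.2²) Hz truncated to ``iapf_bounds``;
    alpha is attenuated and theta/aperiodic exponent elevated relative to the
    normative targets — the characteristic "spectral slowing" profile.
    """
    rng = np.random.default_rng(seed)
    lo, hi = iapf_bounds
    hi = min(hi, NORMATIVE_ALPHA_CENTER)  # subjects start below their ceiling
    while True:
        iapf = rng.normal(IAPF_PRIOR_MEAN, IAPF_PRIOR_SD)
        if lo < iapf < hi:
            break
    alpha = float(np.clip(rng.normal(0.55, 0.1), 0.2, 1.0))
    theta = float(np.clip(rng.normal(0.7, 0.1), 0.3, 1.2))
    expo = float(np.clip(rng.normal(1.5, 0.15), 1.0, 2.2))
    return VirtualSubjectState(
        iapf=float(iapf), alpha_amplitude=alpha, theta_amplitude=theta,
        aperiodic_exponent=expo, responsiveness=responsiveness,
    )


#: Regional scaling of the alpha peak (posterior-dominant rhythm).
_ALPHA_TOPOGRAPHY = {
    "O1": 1.0, "O2": 1.0, "Oz": 1.0,
    "P3": 0.85, "P4": 0.85, "Pz": 0.9, "T5": 0.7, "T6": 0.7,
    "C3": 0.55, "C4": 0.55, "Cz": 0.6, "T3": 0.45, "T4": 0.45,
    "F3": 0.35, "F4": 0.35, "Fz": 0.4, "F7": 0.3, "F8": 0.3,
    "Fp1": 0.25, "Fp2": 0.25,
}

#: Regional scaling of the theta peak (frontal-midline dominant).
_THETA_TOPOGRAPHY = {
    "Fp1": 0.8, "Fp2": 0.8, "F7": 0.85, "F3": 0.95, "Fz": 1.0,
    "F4": 0.95, "F8": 0.85, "T3": 0.7, "C3": 0.8, "Cz": 0.9,
    "C4": 0.8, "T4": 0.7, "T5": 0.6, "P3": 0.65, "Pz": 0.7,
    "P4": 0.65, "T6": 0.6, "O1": 0.5, "O2": 0.5, "Oz": 0.5,
}

THETA_CENTER_FREQ = 6.0   # Hz
ALPHA_BANDWIDTH_SD = 1.0  # Hz
THETA_BANDWIDTH_SD = 1.2  # Hz
APERIODIC_OFFSET = 10.0   # µV²/Hz at 1 Hz
NOISE_FLOOR = 0.05        # µV²/Hz


def subject_models(state: VirtualSubjectState,
                   montage: Montage | None = None) -> dict[str, SpectralModel]:
    """Map the subject's scalar state onto per-channel spectral models."""
    montage = montage or Montage()
    out: dict[str, SpectralModel] = {}
    for ch in montage.channel_labels:
        peaks = []
        a = state.alpha_amplitude * _ALPHA_TOPOGRAPHY.get(ch, 0.5)
        t = state.theta_amplitude * _THETA_TOPOGRAPHY.get(ch, 0.5)
        if t > 0:
            peaks.append(GaussianPeak(THETA_CENTER_FREQ, t, THETA_BANDWIDTH_SD))
        if a > 0:
            peaks.append(GaussianPeak(state.iapf, a, ALPHA_BANDWIDTH_SD))
        out[ch] = SpectralModel(
            noise_floor=NOISE_FLOOR,
            aperiodic_offset=APERIODIC_OFFSET,
            aperiodic_exponent=state.aperiodic_exponent,
            peaks=tuple(peaks),
        )
    return out


# ---------------------------------------------------------------------------
# EDF output (16-bit European Data Format) + JSON truth sidecar
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {value!r} (max {width})")
    return b.ljust(width)


def write_edf(recording: SyntheticRecording, path: str | Path,
              sidecar: bool = True) -> Path:
    """Write the recording as a 16-bit EDF file (physical units µV).

    Data records are one second long; the recording is zero-padded to a whole
    number of records. A ``<name>.truth.json`` sidecar stores the generating
    spectral models and seed when ``sidecar`` is true.
    """
    path = Path(path)
    fs = recording.montage.sampling_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.montage.n_channels
    n = recording.samples.shape[1]
    n_records = int(np.ceil(n / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n] = recording.samples

    phys_max = max(float(np.max(np.abs(padded))), 1.0)
    # the header stores the physical range as 8-char text; quantize against
    # the parsed-back value so writer and reader use identical scaling
    while float(f"{phys_max:.6g}"[:8]) < float(np.max(np.abs(padded))):
        phys_max *= 1.00001
    phys_max = float(f"{phys_max:.6g}"[:8])
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.clip(np.round((padded + phys_max) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),                      # patient id (synthetic)
        _edf_field("Startdate X X X X", 80),            # recording id
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),                             # record duration, s
        _edf_field(str(n_ch), 4),
    ])
    labels = recording.montage.channel_labels
    header += b"".join(_edf_field(f"EEG {ch}", 16) for ch in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)          # transducer
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8) for _ in labels)
    header += b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8) for _ in labels)
    header += b"".join(_edf_field(str(dig_min), 8) for _ in labels)
    header += b"".join(_edf_field(str(dig_max), 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)          # prefilter
    header += b"".join(_edf_field(str(spr), 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record

    if sidecar:
        truth_path = path.with_suffix(path.suffix + ".truth.json")
        payload = {
            "seed": recording.seed,
            "duration": recording.duration,
            "sampling_rate": fs,
            "models": {ch: m.to_dict() for ch, m in recording.truth.items()},
        }
        truth_path.write_text(json.dumps(payload, indent=2))
    return path


def read_truth_sidecar(edf_path: str | Path) -> dict[str, SpectralModel]:
    """Load the ground-truth spectral models written next to an EDF file."""
    p = Path(edf_path)
    sidecar = p.with_suffix(p.suffix + ".truth.json")
    payload = json.loads(sidecar.read_text())
    return {ch: SpectralModel.from_dict(d) for ch, d in payload["models"].items()}


# ---------------------------------------------------------------------------
# YAML generation config
# ---------------------------------------------------------------------------

def load_generation_config(path: str | Path) -> dict:
    """Parse a YAML generation config into synthesize_recording arguments.

    Schema::

        montage:
          channels: [O1, O2, ...]       # default: standard 10–20
          sampling_rate: 256
        duration: 120.0
        seed: 1
        models:
          default: {aperiodic_offset: 10, aperiodic_exponent: 1.5, ...,
                    peaks: [{center_freq: 10, amplitude: 0.8, bandwidth_sd: 1}]}
          O1: {...}                      # per-channel overrides
    """
    cfg = yaml.safe_load(Path(path).read_text())
    mcfg = cfg.get("montage", {})
    montage = Montage(
        channel_labels=tuple(mcfg.get("channels", STANDARD_1020)),
        sampling_rate=float(mcfg.get("sampling_rate", 256.0)),
    )
    model_cfg = cfg.get("models", {})
    default = SpectralModel.from_dict(model_cfg.get("default", {}))
    models = {
        ch: (SpectralModel.from_dict(model_cfg[ch]) if ch in model_cfg else default)
        for ch in montage.channel_labels
    }
    return {
        "models": models,
        "montage": montage,
        "duration": float(cfg.get("duration", 120.0)),
        "seed": int(cfg.get("seed", 0)),
    }
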