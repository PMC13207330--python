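"""Closed-loop session orchestration and offline analysis.

One feedback epoch runs the full loop: the virtual subject's current state
is rendered to per-channel spectral models, one epoch of EEG is synthesized,
the feedback signal y is measured (training-band power for enhance protocols,
Theta/Alpha ratio for suppress), the adaptive controller decides the reward
against its current threshold and then updates its belief, the subject's
plasticity-coupled state advances, and the HRV gate adjusts difficulty.
Deviation metrics (i-APF, both CDI forms) are recomputed on a sliding buffer
of recent epochs; sessions chain into longitudinal programs whose endpoint
is the gradual subtraction of the CDI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from . import bdws, deviation, signal_gen, sourceloc, spectral

logger = logging.getLogger(__name__)

DEFAULT_TARGET_CHANNELS = ("C3", "C4", "Cz")
DEFAULT_TRAINING_BAND = spectral.PRECISION_ALPHA_BAND  # (9.78, 10.25) Hz


@dataclass
class SessionConfig:
    """Everything one session needs; every random draw flows through seeds."""

    subject_seed: int = 0
    responsiveness: float = 0.002
    seed: int = 0                      # session-level noise (EEG, HRV)
    epoch_length: float = 1.0          # s
    session_minutes: float | None = None   # None: take the tier block plan
    tier: str = "auto"                 # auto | HighPerformance | MediumPerformance | HIT
    direction: bdws.Direction = "enhance_y"
    target_success: float = bdws.DEFAULT_TARGET_SUCCESS
    forgetting: float = 0.99
    training_band: tuple[float, float] = DEFAULT_TRAINING_BAND
    target_channels: tuple[str, ...] = DEFAULT_TARGET_CHANNELS
    sampling_rate: float = 256.0
    buffer_epochs: int = 30            # sliding metric buffer
    metrics_period: int = 10           # recompute i-APF/CDI every k epochs
    age: float = 78.0
    hrv_baseline: float = 42.0         # ms RMSSD-like
    hrv_ar: float = 0.9
    hrv_noise_sd: float = 1.5
    hrv_drops: tuple[tuple[int, float, int], ...] = ()  # (epoch, frac, length)
    hrv_ease_step: float = 0.05
    prior_bdws_score: float | None = None  # carries over between sessions


@dataclass
class EpochRecord:
    epoch: int
    y: float
    threshold: float
    rewarded: bool
    trailing_success: float
    iapf: float
    cdi_percent: float
    cdi_euclidean: float
    hrv: float
    hrv_gated: bool
    tier: str


@dataclass
class SessionReport:
    epochs: pd.DataFrame
    start_iapf: float
    end_iapf: float
    start_cdi_percent: float
    end_cdi_percent: float
    start_cdi_euclidean: float
    end_cdi_euclidean: float
    spider_start: deviation.SpiderMapVector
    spider_end: deviation.SpiderMapVector
    tier: bdws.TierAssignment
    bdws_score: float
    subject_end_state: signal_gen.VirtualSubjectState
    seeds: dict[str, int]
    true_end_iapf: float


def _session_channels(config: SessionConfig) -> tuple[str, ...]:
    """Channels the loop actually needs: feedback targets plus i-APF nodes."""
    wanted = list(config.target_channels)
    for ch in signal_gen.IAPF_NODES:
        if ch in signal_gen.STANDARD_1020 and ch not in wanted:
            wanted.append(ch)
    return tuple(wanted)


def _epoch_y(samples: np.ndarray, fs: float, config: SessionConfig) -> float:
    """Feedback signal from one epoch's target-channel samples.

    enhance_y: mean power density in the (narrow) training band, estimated
    on a zero-padded periodogram so sub-Hz bands are resolved.
    suppress_y: Theta/Alpha band-power ratio.
    """
    nper = samples.shape[1]
    f, p = scipy.signal.welch(
        samples, fs=fs, window="hann", nperseg=nper, nfft=max(8 * nper, 2048),
        axis=-1,
    )
    pm = p.mean(axis=0)
    if config.direction == "enhance_y":
        lo, hi = config.training_band
        sel = (f >= lo) & (f <= hi)
        return float(pm[sel].mean())
    theta = (f >= 4.0) & (f <= 8.0)
    alpha = (f >= 8.0) & (f <= 13.0)
    return float(pm[theta].mean() / pm[alpha].mean())


def _measure_iapf(buffer: np.ndarray, fs: float, channels: Sequence[str]) -> float:
    """Per-channel center-of-gravity i-APF over the posterior nodes of the
    buffer, averaged (channels where the fit or the alpha band is empty are
    skipped)."""
    montage = signal_gen.Montage(channel_labels=tuple(channels), sampling_rate=fs)
    rec = signal_gen.SyntheticRecording(
        montage=montage, duration=buffer.shape[1] / fs,
        samples=buffer, truth={ch: signal_gen.SpectralModel() for ch in channels},
        seed=-1,
    )
    spec = spectral.compute_psd(rec)
    values = []
    for ch in channels:
        if ch not in signal_gen.IAPF_NODES:
            continue
        try:
            fit = spectral.fit_aperiodic(spec, channel=ch)
            ps = spectral.extract_peaks(spec, fit, channel=ch)
            values.append(spectral.iapf_center_of_gravity(ps).value)
        except (spectral.FitError, spectral.NoAlphaRhythmError):
            continue
    if not values:
        raise spectral.NoAlphaRhythmError("no posterior channel yielded an i-APF")
    return float(np.mean(values))


def _measure_zmap(buffer: np.ndarray, fs: float, channels: Sequence[str],
                  iapf: float, db, age: float) -> deviation.ZScoreMap:
    montage = signal_gen.Montage(channel_labels=tuple(channels), sampling_rate=fs)
    rec = signal_gen.SyntheticRecording(
        montage=montage, duration=buffer.shape[1] / fs, samples=buffer,
        truth={ch: signal_gen.SpectralModel() for ch in channels}, seed=-1,
    )
    spec = spectral.compute_psd(rec)
    observed: dict[deviation.MetricKey, float] = {}
    for ch in channels:
        for band_name in ("Theta", "Alpha1", "Alpha2"):
            band = spectral.DEFAULT_BANDS[band_name]
            observed[(ch, band_name, "absolute_power")] = spectral.band_power(
                spec, band, channel=ch)
        if ch in signal_gen.IAPF_NODES:
            observed[(ch, "Alpha", "iapf")] = iapf
    return deviation.build_zscore_map(observed, db, age)


def _initial_tier(config: SessionConfig) -> bdws.TierAssignment:
    if config.tier != "auto":
        plans = {t.tier: t for t in
                 (bdws.assign_tier(90.0), bdws.assign_tier(80.0), bdws.assign_tier(50.0))}
        if config.tier not in plans:
            raise ValueError(f"unknown tier {config.tier!r}")
        return plans[config.tier]
    score = config.prior_bdws_score if config.prior_bdws_score is not None else 50.0
    return bdws.assign_tier(score)


def run_session(config: SessionConfig,
                subject: signal_gen.VirtualSubjectState | None = None,
                normative_db: Sequence[deviation.NormativeEntry] | None = None,
                ) -> SessionReport:
    """Run one closed-loop session; fully deterministic under fixed seeds."""
    if subject is None:
        subject = signal_gen.draw_mci_subject(
            config.subject_seed, responsiveness=config.responsiveness)
    db = normative_db if normative_db is not None else deviation.make_synthetic_normative_db()
    channels = _session_channels(config)
    fs = config.sampling_rate
    montage = signal_gen.Montage(channel_labels=channels, sampling_rate=fs)
    n_epoch_samples = int(round(config.epoch_length * fs))

    tier = _initial_tier(config)
    if config.session_minutes is not None:
        phases = [("active", config.session_minutes)]
    else:
        phases = list(tier.block_plan)
    active_epochs = int(sum(m for ph, m in phases if ph == "active") * 60
                        / config.epoch_length)

    posterior = bdws.ThresholdPosterior(
        target_success=config.target_success, direction=config.direction,
        forgetting=config.forgetting)
    base_rho = config.target_success
    rng = np.random.default_rng(config.seed)
    epoch_seeds = rng.integers(0, 2**31 - 1, size=active_epochs)
    hrv_noise = rng.normal(0.0, config.hrv_noise_sd, size=active_epochs)

    buffer: list[np.ndarray] = []
    events: list[bdws.RewardEvent] = []
    records: list[EpochRecord] = []
    hrv_value = config.hrv_baseline
    iapf_meas = float("nan")
    cdi_pct = float("nan")
    cdi_euc = float("nan")
    zmap_start = zmap_end = None
    warmup = 10

    for e in range(active_epochs):
        models = signal_gen.subject_models(subject, montage)
        epoch_rec = signal_gen.synthesize_recording(
            models, montage, max(config.epoch_length, 4.0), seed=int(epoch_seeds[e]))
        # use only the first epoch_length seconds (synthesis needs >= 4 s)
        samples = epoch_rec.samples[:, :n_epoch_samples]
        buffer.append(samples)
        if len(buffer) > config.buffer_epochs:
            buffer.pop(0)

        target_idx = [channels.index(ch) for ch in config.target_channels]
        y = _epoch_y(samples[target_idx], fs, config)

        theta = posterior.threshold
        if e < warmup or theta is None:
            rewarded, theta_out = False, float("nan")
        else:
            rewarded = bdws.reward_decision(y, theta, config.direction)
            theta_out = theta
        posterior = bdws.update_posterior(posterior, y)
        events.append(bdws.RewardEvent(e, y, theta_out, rewarded, config.direction))

        subject = signal_gen.subject_step(subject, rewarded)

        # HRV stream: AR(1) around baseline with optional induced drops
        hrv_value = (config.hrv_baseline
                     + config.hrv_ar * (hrv_value - config.hrv_baseline)
                     + hrv_noise[e])
        for start, frac, length in config.hrv_drops:
            if start <= e < start + length:
                hrv_value = config.hrv_baseline * (1.0 - frac)
        hrv_state = bdws.HRVState(current=hrv_value, baseline=config.hrv_baseline)
        posterior, gated = bdws.hrv_gate(hrv_state, posterior, config.hrv_ease_step)
        if not gated and posterior.target_success != base_rho:
            posterior = replace(posterior, target_success=base_rho)
            if posterior.n_obs > 0:
                posterior = replace(posterior, threshold=posterior.quantile_threshold())

        if (e + 1) % config.metrics_period == 0 and len(buffer) >= min(
                config.buffer_epochs, 10):
            buf = np.concatenate(buffer, axis=1)
            try:
                iapf_meas = _measure_iapf(buf, fs, channels)
                cdi_pct = deviation.cdi_percent(iapf_meas)
                zmap = _measure_zmap(buf, fs, channels, iapf_meas, db, config.age)
                cdi_euc = deviation.cdi_euclidean(zmap)
                if zmap_start is None:
                    zmap_start = zmap
                zmap_end = zmap
            except spectral.NoAlphaRhythmError:
                logger.warning("epoch %d: no measurable alpha rhythm", e)

        trailing = (sum(ev.rewarded for ev in events[-100:])
                    / min(len(events), 100))
        records.append(EpochRecord(
            epoch=e, y=y, threshold=theta_out, rewarded=rewarded,
            trailing_success=trailing, iapf=iapf_meas, cdi_percent=cdi_pct,
            cdi_euclidean=cdi_euc, hrv=hrv_value, hrv_gated=gated,
            tier=tier.tier,
        ))

    if zmap_start is None or zmap_end is None:
        raise RuntimeError("session too short to measure deviation metrics")

    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    score = bdws.bdws_score(events, min(len(events), 200))
    first_metrics = df.dropna(subset=["iapf"]).iloc[0]
    last_metrics = df.dropna(subset=["iapf"]).iloc[-1]
    axis_order = tuple(sorted(zmap_start.entries))
    return SessionReport(
        epochs=df,
        start_iapf=float(first_metrics["iapf"]),
        end_iapf=float(last_metrics["iapf"]),
        start_cdi_percent=float(first_metrics["cdi_percent"]),
        end_cdi_percent=float(last_metrics["cdi_percent"]),
        start_cdi_euclidean=float(first_metrics["cdi_euclidean"]),
        end_cdi_euclidean=float(last_metrics["cdi_euclidean"]),
        spider_start=deviation.spider_map(zmap_start, axis_order),
        spider_end=deviation.spider_map(zmap_end, axis_order),
        tier=tier,
        bdws_score=score,
        subject_end_state=subject,
        seeds={"subject": config.subject_seed, "session": config.seed},
        true_end_iapf=subject.iapf,
    )


@dataclass
class ProgramReport:
    """Longitudinal program: chained sessions with carried-over state."""

    sessions: list[SessionReport]
    cdi_percent_trajectory: list[float]
    iapf_trajectory: list[float]
    cdi_subtraction: float   # median(first 3) − median(last 3) of CDI%


def run_longitudinal(config: SessionConfig, n_sessions: int,
                     normative_db: Sequence[deviation.NormativeEntry] | None = None,
                     ) -> ProgramReport:
    """Chain sessions, carrying over subject state and the BDWS tier score."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    subject = signal_gen.draw_mci_subject(
        config.subject_seed, responsiveness=config.responsiveness)
    db = normative_db if normative_db is not None else deviation.make_synthetic_normative_db()
    reports: list[SessionReport] = []
    score: float | None = config.prior_bdws_score
    for s in range(n_sessions):
        cfg = replace(config, seed=config.seed + 1000 * s, prior_bdws_score=score)
        rep = run_session(cfg, subject=subject, normative_db=db)
        subject = rep.subject_end_state
        score = rep.bdws_score
        reports.append(rep)
    cdi_traj = [r.end_cdi_percent for r in reports]
    iapf_traj = [r.end_iapf for r in reports]
    k = min(3, len(reports))
    subtraction = float(np.median(cdi_traj[:k]) - np.median(cdi_traj[-k:]))
    return ProgramReport(sessions=reports, cdi_percent_trajectory=cdi_traj,
                         iapf_trajectory=iapf_traj, cdi_subtraction=subtraction)


# ---------------------------------------------------------------------------
# Offline analysis of a recording
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    iapf_cog: float
    iapf_top3: float | None
    deviation_hz: float                 # |normative center − i-APF|
    cdi: deviation.CDIResult
    spider: deviation.SpiderMapVector
    per_channel_exponent: dict[str, float]
    roi_powers: dict[str, float] | None
    normative_center: float


def analyze_recording(
    edf_path: str | Path,
    normative_db: Sequence[deviation.NormativeEntry] | str | Path,
    age: float = 78.0,
    normative_center: float = signal_gen.NORMATIVE_ALPHA_CENTER,
    with_sources: bool = False,
) -> AnalysisReport:
    """Offline pipeline: PSD → aperiodic fit → peaks → i-APF (both rules) →
    Z-scores → CDI (both forms) → spider map, optionally a source map with
    DMN ROI powers. No controller is involved."""
    if isinstance(normative_db, (str, Path)):
        db = deviation.read_normative_db(normative_db)
    else:
        db = list(normative_db)
    rec = spectral.load_recording_edf(edf_path)
    spec = spectral.compute_psd(rec)

    exponents: dict[str, float] = {}
    peak_freqs: dict[str, float] = {}
    cog_values: list[float] = []
    observed: dict[deviation.MetricKey, float] = {}
    for ch in rec.montage.channel_labels:
        fit = spectral.fit_aperiodic(spec, channel=ch)
        exponents[ch] = fit.exponent
        ps = spectral.extract_peaks(spec, fit, channel=ch)
        apk = spectral.alpha_peak_frequency(ps)
        if apk is not None:
            peak_freqs[ch] = apk
        if ch in signal_gen.IAPF_NODES:
            try:
                cog_values.append(spectral.iapf_center_of_gravity(ps).value)
            except spectral.NoAlphaRhythmError:
                pass
        for band_name in ("Theta", "Alpha1", "Alpha2"):
            band = spectral.DEFAULT_BANDS[band_name]
            observed[(ch, band_name, "absolute_power")] = spectral.band_power(
                spec, band, channel=ch)

    if not cog_values:
        raise spectral.NoAlphaRhythmError("no posterior channel yielded an i-APF")
    iapf_cog = float(np.mean(cog_values))
    try:
        iapf_top3 = spectral.iapf_top3_average(peak_freqs).value
    except ValueError:
        iapf_top3 = None

    for ch in rec.montage.channel_labels:
        if ch in signal_gen.IAPF_NODES:
            observed[(ch, "Alpha", "iapf")] = iapf_cog
    zmap = deviation.build_zscore_map(observed, db, age)
    cdi = deviation.cdi_result(zmap, iapf_cog, normative_center)
    spider = deviation.spider_map(zmap)

    roi_powers = None
    if with_sources:
        lf, _ = sourceloc.build_toy_headmodel()
        alpha = spectral.DEFAULT_BANDS["Alpha1"]
        values = []
        for ch in lf.sensor_labels:
            if ch in rec.montage.channel_labels:
                values.append(spectral.band_power(spec, alpha, channel=ch))
            else:
                values.append(0.0)
        scalp = sourceloc.ScalpVector(np.sqrt(np.array(values)), lf.sensor_labels)
        smap = sourceloc.localize(scalp, lf)
        roi_powers = {roi: sourceloc.roi_power(smap, roi)
                      for roi in ("Precuneus", "PCC", "other")}

    return AnalysisReport(
        iapf_cog=iapf_cog,
        iapf_top3=iapf_top3,
        deviation_hz=abs(normative_center - iapf_cog),
        cdi=cdi,
        spider=spider,
        per_channel_exponent=exponents,
        roi_powers=roi_powers,
        normative_center=normative_center,
    )


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _session_payload(report: SessionReport) -> dict:
    return {
        "start_iapf": report.start_iapf,
        "end_iapf": report.end_iapf,
        "true_end_iapf": report.true_end_iapf,
        "start_cdi_percent": report.start_cdi_percent,
        "end_cdi_percent": report.end_cdi_percent,
        "start_cdi_euclidean": report.start_cdi_euclidean,
        "end_cdi_euclidean": report.end_cdi_euclidean,
        "bdws_score": report.bdws_score,
        "tier": report.tier.tier,
        "block_plan": list(map(list, report.tier.block_plan)),
        "seeds": report.seeds,
        "epochs": report.epochs.to_dict(orient="list"),
    }


def write_report(report, path: str | Path, format: str = "json") -> Path:
    """Serialize a Session/Program/Analysis report (stable schemas)."""
    path = Path(path)
    if format == "csv":
        if isinstance(report, SessionReport):
            report.epochs.to_csv(path, index=False)
        elif isinstance(report, ProgramReport):
            pd.DataFrame({
                "session": range(len(report.sessions)),
                "end_cdi_percent": report.cdi_percent_trajectory,
                "end_iapf": report.iapf_trajectory,
            }).to_csv(path, index=False)
        elif isinstance(report, AnalysisReport):
            deviation.write_spider_csv(report.spider, path)
        else:
            raise TypeError(f"cannot write {type(report).__name__} as csv")
        return path
    if format != "json":
        raise ValueError(f"unknown format {format!r}")
    if isinstance(report, SessionReport):
        payload = _session_payload(report)
    elif isinstance(report, ProgramReport):
        payload = {
            "n_sessions": len(report.sessions),
            "cdi_percent_trajectory": report.cdi_percent_trajectory,
            "iapf_trajectory": report.iapf_trajectory,
            "cdi_subtraction": report.cdi_subtraction,
            "sessions": [_session_payload(s) for s in report.sessions],
        }
    elif isinstance(report, AnalysisReport):
        payload = {
            "iapf_cog": report.iapf_cog,
            "iapf_top3": report.iapf_top3,
            "deviation_hz": report.deviation_hz,
            "normative_center": report.normative_center,
            "cdi_percent": report.cdi.percent,
            "cdi_percent_display": report.cdi.percent_display,
            "cdi_euclidean": report.cdi.euclidean,
            "per_channel_exponent": report.per_channel_exponent,
            "roi_powers": report.roi_powers,
        }
    else:
        raise TypeError(f"cannot serialize {type(report).__name__}")
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_session_config(path: str | Path) -> SessionConfig:
    """SessionConfig from YAML (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown session config keys: {sorted(unknown)}")
    for key in ("training_band", "target_channels"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "hrv_drops" in raw:
        raw["hrv_drops"] = tuple(tuple(d) for d in raw["hrv_drops"])
    return SessionConfig(**raw)
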