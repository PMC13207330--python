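"""Z-score maps, the Clinical Deviation Index (CDI), spider-map vectors and
normative-database I/O.

The CDI exists in two non-equivalent printed forms, both provided as distinct
named outputs:

* ``cdi_euclidean`` — the aggregate Euclidean distance over standardized
  deviations, ``sqrt(sum_i ((x_i - mu_i) / sigma_i)**2)``;
* ``cdi_percent`` — the i-APF deviation from a normative alpha center as a
  percentage, ``(center - iapf) / center * 100``.

Z-score flags follow the clinical convention used throughout: |z| > 1.5 marks
a training target, |z| >= 2.0 a pathological deviation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_gen import NORMATIVE_ALPHA_CENTER, STANDARD_1020

logger = logging.getLogger(__name__)

TARGET_Z = 1.5        # |z| above this: training target
PATHOLOGICAL_Z = 2.0  # |z| at or above this: pathological

KNOWN_CHANNELS = set(STANDARD_1020) | {"Oz", "A1", "A2", "Fpz", "T7", "T8", "P7", "P8"}
KNOWN_METRICS = ("absolute_power", "relative_power", "coherence", "iapf")

MetricKey = tuple[str, str, str]  # (channel, band, metric)


class NormativeDBError(ValueError):
    """Schema or consistency problem in a normative database."""


@dataclass(frozen=True)
class NormativeEntry:
    """One normative reference value: per channel, band, metric, age stratum."""

    channel: str
    band: str
    metric: str
    mean: float
    sd: float
    age_lo: float
    age_hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise NormativeDBError(
                f"sd must be > 0 for ({self.channel}, {self.band}, {self.metric})"
            )


@dataclass
class ZScoreMap:
    """Standardized deviations keyed by (channel, band, metric)."""

    entries: dict[MetricKey, float]
    flags: dict[MetricKey, str]
    age_stratum: tuple[float, float] | None = None


@dataclass
class SpiderMapVector:
    """Radar-chart vector of |z| radii; the center (radius 0) is the
    normative mean, so shrinkage toward the center is CDI 'subtraction'."""

    axes: tuple[MetricKey, ...]
    radii: np.ndarray
    flags: tuple[str, ...]


@dataclass
class CDIResult:
    """Both printed CDI forms plus the Z-score map they derive from."""

    euclidean: float
    percent: float                 # signed; negative when i-APF exceeds the norm
    percent_display: str           # two-decimal clinical report form
    components: ZScoreMap


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------

def z_flag(z: float) -> str:
    if abs(z) >= PATHOLOGICAL_Z:
        return "pathological"
    if abs(z) > TARGET_Z:
        return "target"
    return "normative"


def zscore(observed: float, norm: NormativeEntry) -> tuple[float, str]:
    """Standardize one observation: ``(observed - mean) / sd`` plus flag."""
    z = (observed - norm.mean) / norm.sd
    return z, z_flag(z)


def build_zscore_map(
    observed: Mapping[MetricKey, float],
    db: Sequence[NormativeEntry],
    age: float,
) -> ZScoreMap:
    """Z-score every observed (channel, band, metric) against the matching
    age stratum; observations with no normative entry raise."""
    stratum = match_stratum(db, age)
    index = {
        (e.channel, e.band, e.metric): e
        for e in db
        if (e.age_lo, e.age_hi) == stratum
    }
    entries: dict[MetricKey, float] = {}
    flags: dict[MetricKey, str] = {}
    for key, value in observed.items():
        if key not in index:
            raise NormativeDBError(f"no normative entry for {key} in stratum {stratum}")
        z, flag = zscore(value, index[key])
        if not math.isfinite(z):
            raise NormativeDBError(f"non-finite z for {key}")
        entries[key] = z
        flags[key] = flag
    return ZScoreMap(entries=entries, flags=flags, age_stratum=stratum)


# ---------------------------------------------------------------------------
# CDI
# ---------------------------------------------------------------------------

def cdi_euclidean(zmap: ZScoreMap,
                  selection: Iterable[MetricKey] | None = None) -> float:
    """Aggregate Euclidean deviation ``sqrt(sum z_i**2)`` over the selection.

    ``selection`` restricts the sum (e.g. to channels mapped onto a source
    ROI); by default every entry contributes.
    """
    keys = list(selection) if selection is not None else list(zmap.entries)
    if not keys:
        raise ValueError("empty selection for cdi_euclidean")
    missing = [k for k in keys if k not in zmap.entries]
    if missing:
        raise KeyError(f"selection keys absent from z-score map: {missing}")
    return float(np.sqrt(sum(zmap.entries[k] ** 2 for k in keys)))


def iapf_deviation(iapf: float,
                   normative_center: float = NORMATIVE_ALPHA_CENTER) -> float:
    """Distance of the i-APF from the normative alpha center, in Hz
    (``center − iapf``; positive for a slowed rhythm)."""
    return normative_center - iapf


def cdi_percent(iapf: float,
                normative_center: float = NORMATIVE_ALPHA_CENTER) -> float:
    """i-APF deviation from the normative alpha center, in percent.

    ``(center - iapf) / center * 100`` — signed: positive for a slowed alpha
    rhythm, negative when the subject's i-APF exceeds the norm. Full float
    precision is returned; use :func:`format_percent` for the two-decimal
    clinical report form.
    """
    if normative_center <= 0:
        raise ValueError("normative_center must be > 0")
    return (normative_center - iapf) / normative_center * 100.0


def format_percent(percent: float) -> str:
    """Two-decimal clinical report form of a CDI percentage.

    Truncates toward zero so a deviation is never over-reported; internal
    computation keeps full precision.
    """
    truncated = math.trunc(percent * 100.0) / 100.0
    return f"{truncated:.2f}"


def cdi_result(zmap: ZScoreMap, iapf: float,
               normative_center: float = NORMATIVE_ALPHA_CENTER) -> CDIResult:
    pct = cdi_percent(iapf, normative_center)
    return CDIResult(
        euclidean=cdi_euclidean(zmap),
        percent=pct,
        percent_display=format_percent(pct),
        components=zmap,
    )


# ---------------------------------------------------------------------------
# Spider maps
# ---------------------------------------------------------------------------

def spider_map(zmap: ZScoreMap,
               axis_order: Sequence[MetricKey] | None = None) -> SpiderMapVector:
    """|z| radii in a stable axis order (sorted keys unless supplied).

    Keeping the axis order fixed across sessions makes longitudinal spider
    maps directly comparable; see :func:`spider_difference`.
    """
    axes = tuple(axis_order) if axis_order is not None else tuple(sorted(zmap.entries))
    missing = [k for k in axes if k not in zmap.entries]
    if missing:
        raise KeyError(f"axis keys absent from z-score map: {missing}")
    radii = np.array([abs(zmap.entries[k]) for k in axes])
    flags = tuple(zmap.flags[k] for k in axes)
    return SpiderMapVector(axes=axes, radii=radii, flags=flags)


def spider_difference(before: SpiderMapVector,
                      after: SpiderMapVector) -> np.ndarray:
    """Per-axis radius change (after − before); all ≤ 0 means uniform
    shrinkage toward the normative center."""
    if before.axes != after.axes:
        raise ValueError("spider maps have mismatched axes; fix axis_order")
    return after.radii - before.radii


# ---------------------------------------------------------------------------
# Normative database I/O
# ---------------------------------------------------------------------------

_DB_COLUMNS = ["channel", "band", "metric", "age_lo", "age_hi", "mean", "sd"]


def read_normative_db(path: str | Path) -> list[NormativeEntry]:
    """Read and validate a normative database CSV.

    Schema: ``channel, band, metric, age_lo, age_hi, mean, sd``. Rejected with
    a row-numbered error: non-positive sd, unknown channel or metric, and
    overlapping age strata for the same (channel, band, metric).
    """
    df = pd.read_csv(path)
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        raise NormativeDBError(f"normative DB missing columns: {missing}")
    entries: list[NormativeEntry] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["sd"] <= 0:
            raise NormativeDBError(f"row {rowno}: sd must be > 0, got {row['sd']}")
        if row["channel"] not in KNOWN_CHANNELS:
            raise NormativeDBError(f"row {rowno}: unknown channel {row['channel']!r}")
        if row["metric"] not in KNOWN_METRICS:
            raise NormativeDBError(f"row {rowno}: unknown metric {row['metric']!r}")
        if not row["age_lo"] < row["age_hi"]:
            raise NormativeDBError(f"row {rowno}: need age_lo < age_hi")
        entries.append(NormativeEntry(
            channel=str(row["channel"]), band=str(row["band"]),
            metric=str(row["metric"]), mean=float(row["mean"]),
            sd=float(row["sd"]),
            age_lo=float(row["age_lo"]), age_hi=float(row["age_hi"]),
        ))
    _check_strata(entries)
    return entries


def _check_strata(entries: Sequence[NormativeEntry]) -> None:
    by_key: dict[MetricKey, list[tuple[float, float]]] = {}
    for e in entries:
        by_key.setdefault((e.channel, e.band, e.metric), []).append((e.age_lo, e.age_hi))
    for key, strata in by_key.items():
        strata = sorted(strata)
        for (lo1, hi1), (lo2, hi2) in zip(strata, strata[1:]):
            if lo2 < hi1:  # [lo, hi) intervals: touching is fine
                raise NormativeDBError(
                    f"overlapping age strata for {key}: [{lo1}, {hi1}) and [{lo2}, {hi2})"
                )


def match_stratum(db: Sequence[NormativeEntry], age: float) -> tuple[float, float]:
    """Return the (age_lo, age_hi) stratum containing ``age``.

    Strata are half-open ``[lo, hi)``, so age 76 against [60, 76) and
    [76, 120) selects the 76+ stratum. Ambiguity (overlap) is rejected at
    read time.
    """
    strata = sorted({(e.age_lo, e.age_hi) for e in db})
    hits = [s for s in strata if s[0] <= age < s[1]]
    if not hits:
        raise NormativeDBError(f"no age stratum covers age {age}")
    return hits[0]


def make_synthetic_normative_db(
    channels: Sequence[str] = STANDARD_1020,
    bands: Sequence[str] = ("Delta", "Theta", "Alpha1", "Alpha2", "Beta1", "Beta2"),
) -> list[NormativeEntry]:
    """A synthetic, non-clinical normative database for tests and simulations.

    Two age strata ([60, 76) and [76, 120)) with plausible absolute band
    powers (µV²) plus an i-APF reference entry per posterior channel. The
    values are fabricated with a mild age-related slowing built in; nothing
    here derives from a real population.
    """
    # plausible absolute band powers, µV², younger stratum
    base_power = {"Delta": 12.0, "Theta": 9.0, "Alpha1": 14.0,
                  "Alpha2": 10.0, "Beta1": 6.0, "Beta2": 3.0}
    aging = {"Delta": 1.1, "Theta": 1.15, "Alpha1": 0.85,
             "Alpha2": 0.8, "Beta1": 0.95, "Beta2": 0.95}
    entries: list[NormativeEntry] = []
    for lo, hi, older in ((60.0, 76.0, False), (76.0, 120.0, True)):
        for ch in channels:
            posterior = ch in ("O1", "O2", "Oz", "P3", "P4", "Pz", "T5", "T6")
            for band in bands:
                mean = base_power[band] * (aging[band] if older else 1.0)
                mean *= 1.4 if (posterior and band.startswith("Alpha")) else 1.0
                entries.append(NormativeEntry(
                    channel=ch, band=band, metric="absolute_power",
                    mean=round(mean, 3), sd=round(0.35 * mean, 3),
                    age_lo=lo, age_hi=hi,
                ))
            if posterior:
                entries.append(NormativeEntry(
                    channel=ch, band="Alpha", metric="iapf",
                    mean=10.25 if not older else 10.0, sd=0.9,
                    age_lo=lo, age_hi=hi,
                ))
    return entries


def write_normative_db(entries: Sequence[NormativeEntry], path: str | Path) -> Path:
    df = pd.DataFrame([{
        "channel": e.channel, "band": e.band, "metric": e.metric,
        "age_lo": e.age_lo, "age_hi": e.age_hi, "mean": e.mean, "sd": e.sd,
    } for e in entries])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_zscore_csv(zmap: ZScoreMap, path: str | Path) -> Path:
    rows = [{"channel": ch, "band": b, "metric": m,
             "z": z, "flag": zmap.flags[(ch, b, m)]}
            for (ch, b, m), z in sorted(zmap.entries.items())]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_cdi_json(result: CDIResult, path: str | Path) -> Path:
    payload = {
        "cdi_euclidean": result.euclidean,
        "cdi_percent": result.percent,
        "cdi_percent_display": result.percent_display,
        "n_components": len(result.components.entries),
        "age_stratum": result.components.age_stratum,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_spider_csv(vec: SpiderMapVector, path: str | Path) -> Path:
    rows = [{"channel": ch, "band": b, "metric": m, "radius": r, "flag": fl}
            for (ch, b, m), r, fl in zip(vec.axes, vec.radii, vec.flags)]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
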