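"""Bayesian Dynamic Weight Shifting (BDWS): the adaptive reward controller.

The feedback signal y (a band-power or power ratio, strictly positive) is
modeled as log-normal. A normal-inverse-gamma belief over (mean, variance) of
log y is updated recursively each epoch,

    P(theta_{t+1} | y_{1:t}) ∝ P(y_t | theta_t) P(theta_t | y_{1:t-1}),

and the reward threshold is reset to the quantile of the posterior-predictive
(Student-t on log y) that yields the target success probability rho*. The
clinical operating point is rho* = 0.70 — the 85% optimal-learning rule minus
a 15% clinical safety offset for populations with degraded SNR. A
distribution-free empirical-quantile tracker is provided as an alternative
backend; both hold the set point on stationary input.

Performance tiers (High ≥ 85%, Medium 75–85%, High-Intensity Training < 75%)
map a trailing BDWS success score onto session block plans, and an HRV gate
eases the operating point when autonomic stress is detected.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.stats

logger = logging.getLogger(__name__)

Direction = Literal["suppress_y", "enhance_y"]

DEFAULT_TARGET_SUCCESS = 0.70   # clinical operating point
HEALTHY_TARGET_SUCCESS = 0.85   # optimal-learning preset
HRV_RHO_CAP = 0.90              # easing never pushes rho* above this


def operating_point(base: float = 0.85, clinical_offset: float = 0.15) -> float:
    """Target success probability: optimum minus the clinical safety offset.

    ``operating_point()`` is the 70% rule; ``operating_point(0.85, 0.0)`` the
    healthy-population 85% rule.
    """
    rho = base - clinical_offset
    if not (0.0 < rho < 1.0):
        raise ValueError(f"operating point must lie in (0, 1), got {rho}")
    return rho


def information_gain(p: float) -> float:
    """Binary entropy H(p) in bits; H(0) = H(1) = 0.

    Learning stalls at both extremes: a task at 100% success carries no
    information, one at 0% is pure noise. H is maximized at p = 0.5 and
    H(0.70) > H(0.85) — the challenge-retention argument for the 70% rule.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


# ---------------------------------------------------------------------------
# Posterior backends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPosterior:
    """Normal-inverse-gamma belief over (location, scale) of log y.

    ``mu, kappa, a, b`` are the standard NIG hyperparameters on log y;
    ``threshold`` is the current reward threshold θ in y units (set after the
    first update). ``update_period`` is the θ refresh interval in seconds
    (one 1-s epoch by default). ``forgetting`` exponentially discounts the
    evidence before each update (power-prior recursion), giving the belief a
    finite memory of roughly ``1 / (1 - forgetting)`` epochs so the threshold
    tracks non-stationary performance; 1.0 recovers the pure conjugate
    recursion.
    """

    mu: float = 0.0
    kappa: float = 0.01
    a: float = 1.0
    b: float = 1.0
    target_success: float = DEFAULT_TARGET_SUCCESS
    direction: Direction = "enhance_y"
    update_period: float = 1.0
    forgetting: float = 0.99
    threshold: float | None = None
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_success < 1.0):
            raise ValueError("target_success must be in (0, 1)")
        if self.direction not in ("suppress_y", "enhance_y"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def predictive(self) -> scipy.stats.rv_continuous:
        """Posterior-predictive distribution of log y (Student-t)."""
        scale = math.sqrt(self.b * (self.kappa + 1.0) / (self.a * self.kappa))
        return scipy.stats.t(df=2.0 * self.a, loc=self.mu, scale=scale)

    def quantile_threshold(self) -> float:
        """θ such that the predicted success probability equals rho*."""
        rho = self.target_success
        q = rho if self.direction == "suppress_y" else 1.0 - rho
        return float(np.exp(self.predictive().ppf(q)))


def update_posterior(posterior: ThresholdPosterior, y: float) -> ThresholdPosterior:
    """One conjugate recursive update followed by the threshold reset.

    Non-positive y cannot arise from a power measure; such epochs are
    rejected (logged) and leave the belief unchanged.
    """
    if y <= 0:
        logger.warning("rejected non-positive feedback sample y=%r", y)
        return posterior
    x = math.log(y)
    lam = posterior.forgetting
    kappa = max(lam * posterior.kappa, 0.01)
    a = max(lam * posterior.a, 1.0)
    b = lam * posterior.b
    kappa_n = kappa + 1.0
    mu_n = (kappa * posterior.mu + x) / kappa_n
    a_n = a + 0.5
    b_n = b + 0.5 * kappa * (x - posterior.mu) ** 2 / kappa_n
    updated = replace(posterior, mu=mu_n, kappa=kappa_n, a=a_n, b=b_n,
                      n_obs=posterior.n_obs + 1)
    return replace(updated, threshold=updated.quantile_threshold())


class EmpiricalQuantileTracker:
    """Distribution-free backend: θ is the rolling empirical quantile of y.

    Mirrors the ThresholdPosterior interface where the controller needs it
    (threshold, target_success, direction, update).
    """

    def __init__(self, target_success: float = DEFAULT_TARGET_SUCCESS,
                 direction: Direction = "enhance_y", window: int = 300):
        if not (0.0 < target_success < 1.0):
            raise ValueError("target_success must be in (0, 1)")
        self.target_success = target_success
        self.direction = direction
        self._buffer: deque[float] = deque(maxlen=window)
        self.threshold: float | None = None

    def update(self, y: float) -> "EmpiricalQuantileTracker":
        if y <= 0:
            logger.warning("rejected non-positive feedback sample y=%r", y)
            return self
        self._buffer.append(y)
        rho = self.target_success
        q = rho if self.direction == "suppress_y" else 1.0 - rho
        self.threshold = float(np.quantile(self._buffer, q))
        return self


# ---------------------------------------------------------------------------
# Reward decisions and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardEvent:
    epoch_index: int
    y: float
    threshold: float
    rewarded: bool
    direction: Direction


def reward_decision(y: float, threshold: float, direction: Direction) -> bool:
    """suppress_y: reward iff y < θ; enhance_y: reward iff y > θ.

    Equality earns no reward (deterministic tie rule).
    """
    if direction == "suppress_y":
        return y < threshold
    if direction == "enhance_y":
        return y > threshold
    raise ValueError(f"unknown direction {direction!r}")


def success_rate(events: Sequence[RewardEvent], window: int) -> float:
    """Rewarded fraction over the trailing ``window`` events."""
    if window <= 0 or not events:
        raise ValueError("window must be positive and events non-empty")
    if window > len(events):
        raise ValueError(f"window {window} exceeds {len(events)} events")
    tail = events[-window:]
    return sum(e.rewarded for e in tail) / window


def run_controller(
    y_stream: Iterable[float],
    posterior: ThresholdPosterior | EmpiricalQuantileTracker,
    warmup: int = 10,
) -> tuple[list[RewardEvent], ThresholdPosterior | EmpiricalQuantileTracker]:
    """Feed a y stream through decide-then-update epochs.

    The first ``warmup`` epochs only update the belief (no threshold exists
    yet to decide against); they emit unrewarded events at θ = NaN.
    """
    events: list[RewardEvent] = []
    is_bayes = isinstance(posterior, ThresholdPosterior)
    for i, y in enumerate(y_stream):
        theta = posterior.threshold
        if i < warmup or theta is None:
            rewarded, theta_out = False, float("nan")
        else:
            rewarded = reward_decision(y, theta, posterior.direction)
            theta_out = theta
        events.append(RewardEvent(epoch_index=i, y=float(y), threshold=theta_out,
                                  rewarded=rewarded, direction=posterior.direction))
        posterior = update_posterior(posterior, y) if is_bayes else posterior.update(y)
    return events, posterior


def write_event_log(events: Sequence[RewardEvent], path) -> None:
    """Write reward events as a CSV audit trail."""
    import pandas as pd

    pd.DataFrame([{
        "epoch_index": e.epoch_index, "y": e.y, "threshold": e.threshold,
        "rewarded": e.rewarded, "direction": e.direction,
    } for e in events]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierAssignment:
    tier: str                                  # HighPerformance | MediumPerformance | HIT
    bdws_score: float                          # %
    block_plan: tuple[tuple[str, float], ...]  # (phase, minutes)

    @property
    def total_minutes(self) -> float:
        return sum(m for _, m in self.block_plan)


def assign_tier(bdws_score: float) -> TierAssignment:
    """Map a BDWS success score (%) onto a session tier and block plan.

    [85, 100] → High-Performance (one 25 min continuous high-reward block);
    [75, 85) → Medium-Performance (20 min block with cognitive exercise);
    [0, 75) → High-Intensity Training (15 min as 5 min active / 5 rest /
    5 active). Boundaries: exactly 85 is High, exactly 75 is Medium.
    """
    if not (0.0 <= bdws_score <= 100.0):
        raise ValueError(f"bdws_score must be in [0, 100], got {bdws_score}")
    if bdws_score >= 85.0:
        return TierAssignment("HighPerformance", bdws_score, (("active", 25.0),))
    if bdws_score >= 75.0:
        return TierAssignment("MediumPerformance", bdws_score, (("active", 20.0),))
    return TierAssignment(
        "HIT", bdws_score,
        (("active", 5.0), ("rest", 5.0), ("active", 5.0)),
    )


def bdws_score(events: Sequence[RewardEvent], window: int) -> float:
    """Trailing success rate as a percentage (the tiering score)."""
    return 100.0 * success_rate(events, window)


# ---------------------------------------------------------------------------
# HRV cross-looping gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRVState:
    """Autonomic state: current and baseline HRV (e.g. RMSSD, ms)."""

    current: float
    baseline: float
    drop_fraction: float = 0.2  # relative drop that triggers easing

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("HRV baseline must be > 0")

    @property
    def dropped(self) -> bool:
        return self.current < (1.0 - self.drop_fraction) * self.baseline


def hrv_gate(
    hrv: HRVState,
    posterior: ThresholdPosterior,
    ease_step: float = 0.05,
) -> tuple[ThresholdPosterior, bool]:
    """Ease training difficulty on an HRV drop.

    When current HRV falls below ``(1 - drop_fraction) * baseline`` the
    effective target success probability is raised by ``ease_step`` (more
    rewards, easier task), capped at 0.90; otherwise the posterior passes
    through unchanged. Returns (posterior, gated_flag).
    """
    if ease_step < 0:
        raise ValueError("ease_step must be >= 0")
    if not hrv.dropped:
        return posterior, False
    eased = min(posterior.target_success + ease_step, HRV_RHO_CAP)
    logger.info("HRV gate: easing rho* %.2f -> %.2f", posterior.target_success, eased)
    out = replace(posterior, target_success=eased)
    if out.n_obs > 0:
        out = replace(out, threshold=out.quantile_threshold())
    return out, True
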