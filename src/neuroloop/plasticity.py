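"""Synaptic-plasticity substrate of the digital twin.

Four classic models, each exposed as a small pure function or state machine:

* Hopfield attractor network — energy ``E = -1/2 Σ w_ij s_i s_j + Σ θ_i s_i``
  with asynchronous sign updates; reward-driven "basin deepening" is a
  Hebbian reinforcement of the target pattern.
* BCM rate-based plasticity — ``dw/dt = φ(y, θ_m) x`` with the quadratic
  nonlinearity ``φ = gain · y (y − θ_m)`` and the standard sliding threshold
  ``θ_m = <y²>/y₀``: LTD below threshold, LTP above.
* Homeostatic synaptic scaling — ``dG/dt = γ (R_target − R)``.
* STDP — exponential pair-based kernel with a hard 40 ms pairing window
  outside which reinforcement fails.

A connectome-coupled rate network (``twin_simulate``) runs the whole-brain
twin at its default operating point: 76 regions, coupling G = 0.015, sigmoid
gain shape d = 0.3, 2000 ms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hopfield network
# ---------------------------------------------------------------------------

@dataclass
class HopfieldNet:
    """Symmetric binary attractor network; states in {-1, +1}."""

    weights: np.ndarray      # (n, n) symmetric, zero diagonal
    states: np.ndarray       # (n,) of ±1
    thresholds: np.ndarray   # (n,)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("weights must have zero diagonal")
        s = np.asarray(self.states)
        if not np.all(np.isin(s, (-1, 1))):
            raise ValueError("states must be ±1")
        self.weights = w
        self.states = s.astype(int)
        self.thresholds = np.asarray(self.thresholds, dtype=float)

    @property
    def n_units(self) -> int:
        return len(self.states)


def hopfield_energy(net: HopfieldNet) -> float:
    """E = −½ Σ_ij w_ij s_i s_j + Σ_i θ_i s_i (full double-sum convention)."""
    s = net.states
    return float(-0.5 * s @ net.weights @ s + net.thresholds @ s)


def hopfield_energy_pairwise(net: HopfieldNet) -> float:
    """E = −Σ_{i<j} w_ij s_i s_j — the threshold-free pairwise convention.

    Equals :func:`hopfield_energy` whenever all thresholds are zero (the
    double sum counts each pair twice, the ½ cancels it).
    """
    s = net.states
    w_upper = np.triu(net.weights, k=1)
    return float(-(s @ w_upper @ s))


def hopfield_step(net: HopfieldNet,
                  update_order: Sequence[int] | int | None = None
                  ) -> tuple[HopfieldNet, bool]:
    """One asynchronous sweep: s_i ← sign(Σ_j w_ij s_j − θ_i), 0 → +1.

    ``update_order`` is a permutation of unit indices or a seed used to draw
    one (None = natural order). Energy never increases; returns the new net
    and whether any unit changed.
    """
    n = net.n_units
    if update_order is None:
        order = range(n)
    elif isinstance(update_order, (int, np.integer)):
        order = np.random.default_rng(int(update_order)).permutation(n)
    else:
        order = list(update_order)
        if sorted(order) != list(range(n)):
            raise ValueError("update_order must be a permutation of unit indices")
    s = net.states.copy()
    changed = False
    for i in order:
        h = net.weights[i] @ s - net.thresholds[i]
        new = 1 if h >= 0 else -1  # sign(0) → +1, deterministic tie rule
        if new != s[i]:
            s[i] = new
            changed = True
    return HopfieldNet(net.weights, s, net.thresholds), changed


def hopfield_relax(net: HopfieldNet, max_sweeps: int = 1000,
                   update_order=None) -> HopfieldNet:
    """Iterate sweeps to a fixed point (guaranteed: finite states, monotone
    energy)."""
    for _ in range(max_sweeps):
        net, changed = hopfield_step(net, update_order)
        if not changed:
            return net
    raise RuntimeError("no fixed point within max_sweeps")  # pragma: no cover


def hebbian_store(patterns: Sequence[Sequence[int]]) -> np.ndarray:
    """Hebbian outer-product weights w_ij = (1/n) Σ_p s_i s_j, zero diagonal."""
    pats = np.asarray(patterns, dtype=float)
    if pats.ndim != 2:
        raise ValueError("patterns must be a list of equal-length ±1 vectors")
    n = pats.shape[1]
    w = pats.T @ pats / n
    np.fill_diagonal(w, 0.0)
    return w


def reinforce_weights(net: HopfieldNet, target_pattern: Sequence[int],
                      rate: float) -> HopfieldNet:
    """Basin deepening: w ← w + rate · (outer(target) − diag).

    Strictly lowers the energy of the target pattern (for rate > 0) while
    keeping the weights symmetric with a zero diagonal.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(target_pattern, dtype=float)
    delta = rate * np.outer(t, t)
    np.fill_diagonal(delta, 0.0)
    return HopfieldNet(net.weights + delta, net.states.copy(), net.thresholds.copy())


def enumerate_fixed_points(net: HopfieldNet) -> list[tuple[int, ...]]:
    """Brute-force fixed points over all 2ⁿ states (oracle; n ≤ ~12)."""
    n = net.n_units
    fixed = []
    for bits in range(2**n):
        s = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
        h = net.weights @ s - net.thresholds
        stable = all((1 if h[i] >= 0 else -1) == s[i] for i in range(n))
        if stable:
            fixed.append(tuple(int(v) for v in s))
    return fixed


def basin_of(net: HopfieldNet, target: Sequence[int]) -> float:
    """Fraction of all 2ⁿ start states whose natural-order dynamics end at
    ``target`` (brute force; small n only)."""
    n = net.n_units
    t = tuple(int(v) for v in target)
    hits = 0
    for bits in range(2**n):
        s = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
        end = hopfield_relax(HopfieldNet(net.weights, s, net.thresholds))
        if tuple(int(v) for v in end.states) == t:
            hits += 1
    return hits / 2**n


# ---------------------------------------------------------------------------
# BCM plasticity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BCMState:
    """One synapse under BCM dynamics."""

    weight: float = 0.0
    presynaptic_input: float = 1.0   # x >= 0
    postsynaptic_activity: float = 0.0  # y
    sliding_threshold: float = 1.0   # θ_m > 0 after burn-in
    phi_gain: float = 1.0
    y0: float = 1.0                  # scale of the sliding rule


def bcm_phi(y: float, theta_m: float, gain: float = 1.0) -> float:
    """Classic BCM nonlinearity φ(y, θ_m) = gain · y · (y − θ_m)."""
    return gain * y * (y - theta_m)


def bcm_dw(state: BCMState) -> float:
    """dw/dt = φ(y, θ_m) · x: LTD for 0 < y < θ_m, zero at y = θ_m, LTP above."""
    if state.presynaptic_input < 0:
        raise ValueError("presynaptic input x must be >= 0")
    return bcm_phi(state.postsynaptic_activity, state.sliding_threshold,
                   state.phi_gain) * state.presynaptic_input


def bcm_threshold_update(state: BCMState, recent_y: Sequence[float]) -> float:
    """Sliding threshold θ_m = <y²> / y₀ over the recent activity window.

    The quadratic mean makes the threshold rise faster than activity itself,
    the saturation guard that stabilizes BCM learning.
    """
    y = np.asarray(recent_y, dtype=float)
    if y.size == 0:
        raise ValueError("recent_y window must be non-empty")
    return float(np.mean(y**2) / state.y0)


# ---------------------------------------------------------------------------
# Homeostatic synaptic scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingState:
    """Global multiplicative scaling factor G driven toward a target rate."""

    global_factor: float = 1.0   # G > 0
    firing_rate: float = 0.0     # R
    target_rate: float = 5.0     # R_target
    rate_constant: float = 0.1   # γ > 0

    def __post_init__(self) -> None:
        if self.global_factor <= 0:
            raise ValueError("G must be > 0")
        if self.rate_constant <= 0:
            raise ValueError("γ must be > 0")


def scaling_dG(state: ScalingState) -> float:
    """dG/dt = γ (R_target − R): upscale when underactive, downscale when
    overactive."""
    return state.rate_constant * (state.target_rate - state.firing_rate)


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STDPKernel:
    """Exponential pair-based STDP kernel with a hard pairing window.

    W(Δt) = A⁺ exp(−Δt/τ) for 0 < Δt < cutoff (post after pre: LTP),
    −A⁻ exp(Δt/τ) for −cutoff < Δt < 0 (pre after post: LTD), and 0 for
    |Δt| ≥ cutoff or Δt = 0 — timing outside the window earns nothing.
    """

    potentiation_amp: float = 1.0   # A+
    depression_amp: float = 1.0     # A−
    time_constant: float = 20.0     # τ, ms
    cutoff_window: float = 40.0     # ms

    def __post_init__(self) -> None:
        if self.potentiation_amp < 0 or self.depression_amp < 0:
            raise ValueError("STDP amplitudes must be >= 0")
        if self.cutoff_window <= 0:
            raise ValueError("cutoff window must be > 0")

    def __call__(self, dt: float) -> float:
        if dt == 0 or abs(dt) >= self.cutoff_window:
            return 0.0
        if dt > 0:
            return self.potentiation_amp * np.exp(-dt / self.time_constant)
        return -self.depression_amp * np.exp(dt / self.time_constant)


def stdp_dw(pre_spikes: Sequence[float], post_spikes: Sequence[float],
            kernel: STDPKernel) -> float:
    """Δw = Σ_pre Σ_post W(t_post − t_pre) over all spike pairs (times in ms)."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if np.any(np.diff(pre) < 0) or np.any(np.diff(post) < 0):
        raise ValueError("spike times must be sorted")
    if pre.size == 0 or post.size == 0:
        return 0.0
    dt = post[None, :] - pre[:, None]
    w = np.zeros_like(dt)
    ltp = (dt > 0) & (dt < kernel.cutoff_window)
    ltd = (dt < 0) & (dt > -kernel.cutoff_window)
    w[ltp] = kernel.potentiation_amp * np.exp(-dt[ltp] / kernel.time_constant)
    w[ltd] = -kernel.depression_amp * np.exp(dt[ltd] / kernel.time_constant)
    return float(w.sum())


# ---------------------------------------------------------------------------
# Whole-brain rate-network twin
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwinConfig:
    """Connectome-coupled rate simulation at the default operating point:
    76 regions, coupling strength G = 0.015, sigmoid gain shape d = 0.3,
    2000 ms at 1 ms steps."""

    n_regions: int = 76
    coupling_strength: float = 0.015
    hill_coefficient: float = 0.3
    duration_ms: float = 2000.0
    dt_ms: float = 1.0
    tau_ms: float = 10.0
    noise_sd: float = 0.01
    external_input: float = 0.0
    seed: int = 0
    connectome: np.ndarray | None = None  # region × region, nonneg, zero diag

    def resolved_connectome(self) -> np.ndarray:
        c = self.connectome
        if c is None:
            c = synthetic_connectome(self.n_regions, seed=self.seed)
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_regions, self.n_regions):
            raise ValueError("connectome shape does not match n_regions")
        if np.any(c < 0) or not np.allclose(np.diag(c), 0.0):
            raise ValueError("connectome must be nonnegative with zero diagonal")
        return c


def synthetic_connectome(n_regions: int = 76, seed: int = 0) -> np.ndarray:
    """Seeded synthetic structural connectome (stand-in for an atlas-based
    parcellation): symmetric, nonnegative, zero diagonal, distance-dependent
    connection strength with log-normal weight scatter, row-normalized."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n_regions, 3))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    w = np.exp(-d / 0.7) * rng.lognormal(0.0, 0.5, size=d.shape)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True).mean()  # scale-free normalization
    return w


@dataclass
class TwinReport:
    """Stability diagnostics of a twin run."""

    region_variance: np.ndarray     # temporal variance per region
    mean_synchrony: float           # mean pairwise correlation
    settled: bool                   # post-transient drift below tolerance
    diverged: bool
    final_rates: np.ndarray
    drift: float


def twin_simulate(config: TwinConfig,
                  drift_tolerance: float = 1e-3) -> tuple[np.ndarray, TwinReport]:
    """Euler-integrate the coupled rate network and report stability.

    Dynamics per region: τ dr/dt = −r + S(G Σ_j C_ij r_j + I) with the
    logistic activation S(u) = 1 / (1 + exp(−(u − ½)/d)); seeded Gaussian
    noise of SD ``noise_sd`` enters each step scaled by √dt. ``settled``
    means the drift of the network-mean rate over the last quarter of the
    run stays below ``drift_tolerance`` per ms; divergence is flagged in the
    report, never raised.
    """
    c = config.resolved_connectome()
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration_ms / config.dt_ms))
    n = config.n_regions
    rates = np.zeros((n_steps + 1, n))
    rates[0] = rng.uniform(0.0, 0.2, size=n)
    dt, tau = config.dt_ms, config.tau_ms
    d = config.hill_coefficient
    g = config.coupling_strength
    diverged = False
    for t in range(n_steps):
        r = rates[t]
        u = g * (c @ r) + config.external_input
        s_act = 1.0 / (1.0 + np.exp(-(u - 0.5) / d))
        noise = config.noise_sd * np.sqrt(dt) * rng.standard_normal(n)
        rates[t + 1] = r + dt / tau * (-r + s_act) + noise
        if not np.all(np.isfinite(rates[t + 1])) or np.any(np.abs(rates[t + 1]) > 1e6):
            diverged = True
            rates = rates[: t + 2]
            break

    tail = rates[-max(len(rates) // 4, 2):]
    mean_trace = tail.mean(axis=1)
    drift = float(abs(mean_trace[-1] - mean_trace[0]) / (len(mean_trace) * dt))
    settled = (not diverged) and drift < drift_tolerance
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(tail.T)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    sync = float(np.nanmean(off)) if off.size else 1.0
    report = TwinReport(
        region_variance=tail.var(axis=0),
        mean_synchrony=sync,
        settled=settled,
        diverged=diverged,
        final_rates=rates[-1],
        drift=drift,
    )
    return rates, report


def write_connectome_csv(connectome: np.ndarray, path: str | Path) -> Path:
    """Serialize a region × region coupling matrix as CSV."""
    import pandas as pd

    labels = [f"r{i}" for i in range(connectome.shape[0])]
    path = Path(path)
    pd.DataFrame(connectome, index=labels, columns=labels).to_csv(
        path, index_label="region")
    return path


def write_trajectories_csv(trajectories: np.ndarray, path: str | Path,
                           dt_ms: float = 1.0) -> Path:
    """Serialize twin rate trajectories (time rows × region columns)."""
    import pandas as pd

    df = pd.DataFrame(trajectories,
                      columns=[f"r{i}" for i in range(trajectories.shape[1])])
    df.insert(0, "t_ms", np.arange(trajectories.shape[0]) * dt_ms)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_twin_report(report: TwinReport, path: str | Path) -> Path:
    payload = {
        "settled": bool(report.settled),
        "diverged": bool(report.diverged),
        "drift_per_ms": report.drift,
        "mean_synchrony": report.mean_synchrony,
        "mean_region_variance": float(report.region_variance.mean()),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
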