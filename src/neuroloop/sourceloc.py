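"""Toy-scale distributed EEG source localization (sLORETA).

A fixed-orientation (radial) dipole forward model on a unit spherical head
with the 19 standard 10–20 sensors, a Laplacian-regularized minimum-norm
inverse

    J_hat = argmin_J ||V - L J||^2 + alpha ||B J||^2,

and sLORETA standardization: each voxel estimate divided by the square root
of its resolution-derived variance. For the classic (identity-prior)
standardization the variance matrix equals the resolution matrix
``M = L^T (L L^T + alpha I)^-1 L``, which is symmetric positive semidefinite;
by the Cauchy–Schwarz inequality ``M[v, v0]^2 <= M[v, v] * M[v0, v0]`` the
standardized score of a noiseless single source at v0 is maximized exactly at
v0 — the zero-localization-error property. With the Laplacian-weighted
penalty that exactness is no longer guaranteed, so standardization defaults
to the classic form while the Eq.-style Laplacian inverse remains available
for current-density estimates.

Voxels carry toy ROI labels: a posterior-midline superior block is tagged
"Precuneus" and the block beneath it "PCC" — the DMN hubs this framework
targets. These are coarse blocks in a unit head frame, not atlas structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

CONDITION_WARN_THRESHOLD = 1e12

#: Approximate unit-sphere positions of the 19 standard 10–20 electrodes
#: (x = right, y = anterior, z = superior).
TEN_TWENTY_POSITIONS: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.31, 0.95, 0.05), "Fp2": (0.31, 0.95, 0.05),
    "F7": (-0.81, 0.59, 0.05), "F3": (-0.55, 0.67, 0.50),
    "Fz": (0.0, 0.72, 0.69), "F4": (0.55, 0.67, 0.50),
    "F8": (0.81, 0.59, 0.05),
    "T3": (-1.0, 0.0, 0.05), "C3": (-0.72, 0.0, 0.69),
    "Cz": (0.0, 0.0, 1.0), "C4": (0.72, 0.0, 0.69),
    "T4": (1.0, 0.0, 0.05),
    "T5": (-0.81, -0.59, 0.05), "P3": (-0.55, -0.67, 0.50),
    "Pz": (0.0, -0.72, 0.69), "P4": (0.55, -0.67, 0.50),
    "T6": (0.81, -0.59, 0.05),
    "O1": (-0.31, -0.95, 0.05), "O2": (0.31, -0.95, 0.05),
}


@dataclass
class LeadField:
    """Sensor × voxel gain matrix with geometry metadata."""

    matrix: np.ndarray                  # (n_sensors, n_voxels)
    sensor_labels: tuple[str, ...]
    voxel_positions: np.ndarray         # (n_voxels, 3), unit head frame
    roi_labels: tuple[str, ...]         # per voxel: Precuneus | PCC | other
    condition_number: float
    full_column_rank: bool
    average_referenced: bool = True


@dataclass
class LaplacianOperator:
    """Discrete Laplacian over the voxel adjacency graph (symmetric, zero
    row sums)."""

    matrix: np.ndarray


@dataclass
class ScalpVector:
    """Per-sensor potentials (µV), average-referenced before inversion."""

    values: np.ndarray
    sensor_labels: tuple[str, ...]

    def average_referenced(self) -> "ScalpVector":
        return ScalpVector(self.values - self.values.mean(), self.sensor_labels)


@dataclass
class CurrentDensity:
    """Per-voxel current estimate from the regularized inverse."""

    values: np.ndarray
    regularization: float
    residual_norm: float


@dataclass
class StandardizedSourceMap:
    """Squared standardized voxel scores; peak_voxel ties break low."""

    scores: np.ndarray
    peak_voxel: int
    roi_labels: tuple[str, ...]

    def tied_peaks(self, rtol: float = 1e-9) -> list[int]:
        top = self.scores[self.peak_voxel]
        return [int(i) for i in np.flatnonzero(self.scores >= top * (1 - rtol))]


# ---------------------------------------------------------------------------
# Head model
# ---------------------------------------------------------------------------

def _voxel_grid(n_voxels: int, radius: float = 0.78) -> np.ndarray:
    """Deterministic grid of voxel centers inside a sphere of given radius.

    The grid spacing is refined until at least n_voxels interior points
    exist; the first n_voxels sorted by (z, y, x) are kept.
    """
    for n_side in range(3, 40):
        axis = np.linspace(-radius, radius, n_side)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        pts = pts[np.linalg.norm(pts, axis=1) > 0.05]  # radial moment needs |r|>0
        if len(pts) >= n_voxels:
            order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))
            pts = pts[order]
            # even stride keeps the subsample spatially spread
            keep = np.round(np.linspace(0, len(pts) - 1, n_voxels)).astype(int)
            return pts[keep]
    raise ValueError(f"cannot place {n_voxels} voxels")


def _roi_labels(voxels: np.ndarray) -> tuple[str, ...]:
    """Toy DMN hub blocks: posterior midline, superior (Precuneus) and
    inferior (PCC), beneath the parietal/midline sensors."""
    labels = []
    for x, y, z in voxels:
        if abs(x) <= 0.30 and y <= -0.20:
            labels.append("Precuneus" if z >= 0.15 else "PCC")
        else:
            labels.append("other")
    return tuple(labels)


def _radial_dipole_gain(sensors: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Gain of a radially oriented unit dipole in a spherical conductor
    (homogeneous-sphere potential; the concentric shells contribute a common
    attenuation factor that is absorbed into the units)."""
    n_s, n_v = len(sensors), len(voxels)
    g = np.empty((n_s, n_v))
    moments = voxels / np.linalg.norm(voxels, axis=1, keepdims=True)
    for j in range(n_v):
        d = sensors - voxels[j]
        dist = np.linalg.norm(d, axis=1)
        g[:, j] = d @ moments[j] / dist**3
    return g


def build_toy_headmodel(
    n_sensors: int = 19,
    n_voxels: int = 64,
    geometry: str = "spherical",
    seed: int = 0,
) -> tuple[LeadField, LaplacianOperator]:
    """Build the toy lead field and voxel-graph Laplacian.

    ``spherical`` places the 19 standard 10–20 sensors on the unit sphere
    and voxels on an interior grid with radial-dipole gains; ``random``
    draws a seeded well-conditioned matrix for property tests. Columns are
    average-referenced (sensor mean removed) to match the reference
    convention enforced on scalp data.
    """
    if n_voxels < n_sensors:
        raise ValueError("need n_voxels >= n_sensors")
    if geometry == "spherical":
        if n_sensors != 19:
            raise ValueError("spherical toy model uses the 19 standard sensors")
        labels = tuple(TEN_TWENTY_POSITIONS)
        sensors = np.array([TEN_TWENTY_POSITIONS[ch] for ch in labels])
        sensors /= np.linalg.norm(sensors, axis=1, keepdims=True)
        voxels = _voxel_grid(n_voxels)
        gain = _radial_dipole_gain(sensors, voxels)
    elif geometry == "random":
        rng = np.random.default_rng(seed)
        labels = tuple(f"S{i:02d}" for i in range(n_sensors))
        raw = rng.standard_normal((n_sensors, n_voxels))
        u, _, vt = np.linalg.svd(raw, full_matrices=False)
        s = np.linspace(2.0, 1.0, min(n_sensors, n_voxels))
        gain = u @ np.diag(s) @ vt
        voxels = rng.uniform(-0.7, 0.7, size=(n_voxels, 3))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    avg_ref = geometry == "spherical"
    if avg_ref:
        gain = gain - gain.mean(axis=0, keepdims=True)  # average reference
    sv = np.linalg.svd(gain, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    cond = float(sv[0] / sv[rank - 1])  # effective condition (avg reference
    # removes one dimension from row space by construction)
    full_rank = rank >= min(gain.shape) - 1
    if cond > CONDITION_WARN_THRESHOLD:
        logger.warning("lead field condition number %.3g above threshold", cond)

    lf = LeadField(matrix=gain, sensor_labels=labels, voxel_positions=voxels,
                   roi_labels=_roi_labels(voxels), condition_number=cond,
                   full_column_rank=full_rank, average_referenced=avg_ref)
    return lf, _graph_laplacian(voxels)


def _graph_laplacian(voxels: np.ndarray, k: int = 6) -> LaplacianOperator:
    """Symmetrized k-nearest-neighbour graph Laplacian (D − A)."""
    n = len(voxels)
    d2 = np.sum((voxels[:, None, :] - voxels[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    adj = np.zeros((n, n))
    for i in range(n):
        nearest = np.argsort(d2[i])[:k]
        adj[i, nearest] = 1.0
    adj = np.maximum(adj, adj.T)
    lap = np.diag(adj.sum(axis=1)) - adj
    return LaplacianOperator(matrix=lap)


# ---------------------------------------------------------------------------
# Forward / inverse / standardization
# ---------------------------------------------------------------------------

def forward(leadfield: LeadField, current: np.ndarray,
            noise_sd: float = 0.0, seed: int | None = None) -> ScalpVector:
    """V = L·J + ε with seeded i.i.d. Gaussian sensor noise."""
    current = np.asarray(current, dtype=float)
    if current.shape != (leadfield.matrix.shape[1],):
        raise ValueError(
            f"current density length {current.shape} does not match "
            f"{leadfield.matrix.shape[1]} voxels"
        )
    v = leadfield.matrix @ current
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return ScalpVector(values=v, sensor_labels=leadfield.sensor_labels)


def inverse_minimum_norm(
    scalp: ScalpVector,
    leadfield: LeadField,
    laplacian: LaplacianOperator | None = None,
    alpha: float = 1e-3,
) -> CurrentDensity:
    """Closed-form solution of the penalized least squares.

    Solves ``(LᵀL + α BᵀB) J = Lᵀ V`` (normal equations); with ``laplacian``
    None the penalty is the identity (classic Tikhonov / minimum norm). At
    α = 0 a pseudoinverse is used; a numerically singular system raises with
    advice to set α > 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    L = leadfield.matrix
    v = (scalp.average_referenced().values if leadfield.average_referenced
         else scalp.values)
    if alpha == 0:
        j, *_ = np.linalg.lstsq(L, v, rcond=1e-10)
        if not np.all(np.isfinite(j)):
            raise np.linalg.LinAlgError(
                "singular system at alpha = 0; use alpha > 0")
    else:
        if laplacian is None:
            penalty = np.eye(L.shape[1])
        else:
            penalty = laplacian.matrix.T @ laplacian.matrix
        a_mat = L.T @ L + alpha * penalty
        try:
            j = np.linalg.solve(a_mat, L.T @ v)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular regularized system (alpha={alpha}); "
                "increase alpha or use the identity penalty"
            ) from err
    residual = float(np.linalg.norm(v - L @ j))
    return CurrentDensity(values=j, regularization=alpha, residual_norm=residual)


def sloreta_standardize(
    current: CurrentDensity,
    leadfield: LeadField,
    laplacian: LaplacianOperator | None = None,
) -> StandardizedSourceMap:
    """Standardize a current-density estimate into sLORETA scores.

    Scores are the squared estimates divided by the diagonal of the
    resolution-derived variance ``S = T C Tᵀ`` with ``C = L Lᵀ + α I`` and
    ``T`` the inverse operator matching ``current`` (identity penalty when
    ``laplacian`` is None). For the identity penalty ``S`` reduces to the
    resolution matrix, which makes single-source localization exact.
    """
    L = leadfield.matrix
    alpha = current.regularization
    n_vox = L.shape[1]
    if laplacian is None:
        penalty = np.eye(n_vox)
    else:
        penalty = laplacian.matrix.T @ laplacian.matrix
    a_mat = L.T @ L + alpha * penalty
    t_op = np.linalg.solve(a_mat, L.T)             # (n_vox, n_sensors)
    c_mat = L @ L.T + alpha * np.eye(L.shape[0])
    variance = np.einsum("vs,st,vt->v", t_op, c_mat, t_op)
    if np.any(variance <= 0):
        bad = int(np.argmin(variance))
        raise FloatingPointError(
            f"non-positive standardization variance at voxel {bad} "
            f"({variance[bad]:.3g}); the lead field may be rank-deficient there"
        )
    scores = current.values**2 / variance
    # lowest index among scores within numerical tolerance of the maximum
    # (documented tie rule; robust to floating-point jitter between
    # physically indistinguishable voxels)
    top = float(np.max(scores))
    peak = int(np.flatnonzero(scores >= top * (1.0 - 1e-9))[0])
    return StandardizedSourceMap(scores=scores, peak_voxel=peak,
                                 roi_labels=leadfield.roi_labels)


def localize(scalp: ScalpVector, leadfield: LeadField,
             alpha: float = 1e-3) -> StandardizedSourceMap:
    """Convenience pipeline: classic regularized inverse + standardization."""
    j = inverse_minimum_norm(scalp, leadfield, laplacian=None, alpha=alpha)
    return sloreta_standardize(j, leadfield, laplacian=None)


def roi_power(source_map: StandardizedSourceMap, roi: str) -> float:
    """Mean standardized score over the voxels of one ROI label."""
    idx = [i for i, lab in enumerate(source_map.roi_labels) if lab == roi]
    if not idx:
        raise ValueError(f"ROI {roi!r} has no voxels in this model")
    return float(np.mean(source_map.scores[idx]))


def write_leadfield_csv(leadfield: LeadField, path) -> None:
    """Serialize the gain matrix with sensor rows and voxel columns."""
    import pandas as pd

    df = pd.DataFrame(leadfield.matrix,
                      index=list(leadfield.sensor_labels),
                      columns=[f"v{i}" for i in range(leadfield.matrix.shape[1])])
    df.to_csv(path, index_label="sensor")


def write_source_map_csv(source_map: StandardizedSourceMap,
                         leadfield: LeadField, path) -> None:
    """Per-voxel standardized scores with positions and ROI labels."""
    import pandas as pd

    pos = leadfield.voxel_positions
    pd.DataFrame({
        "voxel": range(len(source_map.scores)),
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "roi": source_map.roi_labels,
        "score": source_map.scores,
        "is_peak": [i == source_map.peak_voxel
                    for i in range(len(source_map.scores))],
    }).to_csv(path, index=False)


def choose_alpha_lcurve(
    scalp: ScalpVector,
    leadfield: LeadField,
    laplacian: LaplacianOperator | None = None,
    grid: Sequence[float] | None = None,
) -> float:
    """Pick α at the L-curve corner (maximum curvature on the log-log
    residual-vs-penalty curve) over a log grid."""
    if grid is None:
        grid = np.logspace(-6, 1, 15)
    rho, eta = [], []
    for a in grid:
        j = inverse_minimum_norm(scalp, leadfield, laplacian, alpha=float(a))
        pen = (laplacian.matrix @ j.values if laplacian is not None else j.values)
        rho.append(max(j.residual_norm, 1e-300))
        eta.append(max(float(np.linalg.norm(pen)), 1e-300))
    x, y = np.log(rho), np.log(eta)
    # curvature via central differences on the parameterized curve
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    denom = (dx**2 + dy**2) ** 1.5
    curv = np.where(denom > 0, np.abs(dx * ddy - dy * ddx) / np.maximum(denom, 1e-300), 0.0)
    return float(grid[int(np.argmax(curv))])
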