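# Methods

This note documents the models implemented in `neuroloop`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate about real EEG.

## Spectral model and synthesis

Each channel's one-sided power spectral density is
`P(f) = L + k·f^(−x) + Σ aᵢ·exp(−(f−fᵢ)²/(2σᵢ²))` in µV²/Hz. The aperiodic
term is interpreted as `k·f^(−x)` (the 1/f form whose exponent is the
log-log slope); `L` is an additive white-noise floor capturing amplifier and
high-frequency background that a pure power law cannot. Time series are
produced by spectral shaping: the rFFT of unit-variance white Gaussian noise
is multiplied by `sqrt(P(f)·fs/2)` and inverted. This gives realistic phase
randomness (unlike summed sinusoids) and makes the Welch estimate of the
output converge to the model PSD. The DC bin is zeroed; EEG is AC-coupled.
Generation is deterministic per (models, montage, duration, seed).

What the generator emulates: 10–20 montage channel labels, posterior-dominant
alpha and frontal-midline theta topography, the aperiodic slope, and the MCI
profile (slowed i-APF drawn from Normal(9.2, 1.2²) Hz truncated to (7, 12),
attenuated alpha, elevated theta and 1/f exponent). What it does not:
volume-conduction mixing between channels (channels are spectrally shaped
independently; the forward model lives in the source-localization layer),
ocular/muscle artifacts, non-stationarity within an epoch, and line noise.
Consequently, passing recovery tests show the estimators are correct and
well-calibrated under the stated model — not that they are robust to real
recording artifacts.

## Aperiodic fitting and peak extraction

`fit_aperiodic` seeds `(k, x)` with a robust log-log linear fit that
iteratively masks bins sitting more than 2.5 residual SDs above the running
fit (this removes oscillatory peaks, which only ever bias the fit upward).
The full model including `L ≥ 0` is then refined by nonlinear least squares
in log space on the masked bins, re-masking against the refined model up to
three times; the floored variant is kept only when it lowers the masked
log-space MSE. Degenerate inputs: an exactly flat spectrum short-circuits
the masking loop (zero residual SD); fewer than 10 usable bins raise a
`FitError`. Default fit range 1–40 Hz.

Peak extraction is greedy: the largest residual bin (ties broken toward the
lower frequency) seeds a Gaussian fit in a ±3 Hz window, which is subtracted
before the next round. The working residual is deliberately *not* floored at
zero — clipping noise at zero biases fitted centers and amplitudes upward —
while the stored flattened spectrum used as a center-of-gravity weight
function is clipped, as a weight must be. Peak bandwidths are constrained to
0.25–4 Hz; fitted amplitudes below `min_amplitude` (default 0.05 µV²/Hz) are
discarded.

Welch defaults are 2 s Hann windows with 50% overlap (0.5 Hz resolution).

## i-APF and the Clinical Deviation Index

The center-of-gravity i-APF is `Σ f·P̃(f) / Σ P̃(f)` over the alpha search
band (default 7–13 Hz) of the flattened spectrum — the "pure" i-APF. It is
computed per channel and averaged over the posterior nodes; a
Gaussian prior window (9.2, 1.2 Hz) can optionally multiply the weights but
is off by default to keep the estimator unbiased. The top-3 rule averages
the three highest per-node alpha peak frequencies over O1/O2/Oz/P3/P4/Pz and
falls back (with an explicit error message) to the center of gravity when
fewer than three nodes show a peak.

The CDI has two non-equivalent printed forms and both are first-class
outputs, never reconciled: the Euclidean z-score norm and the i-APF
percentage `(center − iapf)/center × 100` against a configurable normative
alpha center (default 10.25 Hz). CDI% is signed — negative when the i-APF
exceeds the norm. Displayed percentages are truncated toward zero at two
decimals so a deviation is never over-reported; full precision is kept
internally. Z-score flags: |z| > 1.5 is a training target, |z| ≥ 2.0
pathological.

The packaged normative database is synthetic and non-clinical: two age
strata ([60, 76) and [76, 120) years, half-open so age 76 falls in the older
stratum) with plausible band powers and a mild built-in age-related slowing.
It exists so the z-scoring machinery is exercised end to end; absolute
Euclidean CDI values under it carry no clinical meaning.

## Source localization

The toy head model places the 19 standard 10–20 sensors on a unit sphere
and voxels on an interior grid (radius 0.78, evenly subsampled), with
radially oriented unit dipoles and homogeneous-sphere gains; concentric-shell
attenuation would only contribute a common factor absorbed into the units.
Fixed radial orientation keeps one gain per voxel, which is what makes exact
localization testable at 19 sensors. The gain matrix is average-referenced,
matching the reference enforced on scalp vectors. Posterior-midline voxel
blocks are labeled Precuneus (superior) and PCC (inferior); these are
coarse blocks in the unit head frame, not atlas structures.

The inverse solves `(LᵀL + αBᵀB)J = LᵀV` in closed form. `B` may be the
voxel-graph Laplacian (symmetric k-NN graph, k = 6, zero row sums) or the
identity. Standardization divides each voxel estimate by the square root of
the diagonal of `S = T·C·Tᵀ` with `C = LLᵀ + αI`. For the identity penalty,
`S` collapses to the resolution matrix `M = Lᵀ(LLᵀ+αI)⁻¹L`, which is
symmetric positive semidefinite; Cauchy–Schwarz on `M` then guarantees that
a noiseless single source at voxel v peaks exactly at v for any α > 0 —
the zero-localization-error property, verified for every voxel in the tests.
With the Laplacian penalty that exactness is lost (we measured 15/64 voxels
mislocalized at α = 10⁻³), so the standardized pipeline defaults to the
identity penalty while the Laplacian inverse remains available for
current-density estimates. Peak-voxel ties (physically indistinguishable
voxels) break to the lowest index within a 10⁻⁹ relative tolerance.

A "no fixed bias" check drives the map with diffuse random source activity
plus sensor noise matching the model covariance `LLᵀ + αI`; under that input
the peak voxel spreads over the head (chi-squared over spatial octants,
not rejected at the 0.01 level). Under *white* sensor noise alone the peak
distribution is provably non-uniform — classic standardization assumes the
model covariance — which is a property of sLORETA, not a defect of the
implementation. α defaults to 10⁻³; an L-curve corner picker over a log grid
is provided and records its choice.

## The BDWS controller

The feedback signal y (a band power or band-power ratio, strictly positive)
is modeled as log-normal. The belief over (mean, variance) of log y is a
normal-inverse-gamma posterior updated conjugately each epoch; the reward
threshold is then reset to the quantile of the posterior-predictive
Student-t that makes the predicted success probability equal ρ\*
(suppress: the ρ\* quantile, enhance: the 1−ρ\* quantile). Equality at the
threshold earns no reward. Non-positive samples are rejected and logged.

The likelihood was an open choice: log-normal was selected because power
ratios are positive and right-skewed and the recursion stays closed-form. A
distribution-free rolling-quantile tracker is provided as an alternative
backend; both hold the set point within ±0.03 on stationary streams.

Evidence is discounted by a forgetting factor λ = 0.99 before each update
(power-prior recursion), giving the belief a memory of roughly 100 epochs.
Without forgetting, the pure conjugate recursion weighs all history equally
and cannot track a drifting subject; with it, the controller returns to
within ±0.05 of the set point roughly 400 epochs after a step change in the
y distribution, where a frozen threshold drifts to near-certain reward.
The update period is one 1-s epoch.

The BDWS score used for tiering is the trailing rewarded fraction (200-epoch
window by default), in percent. Tier bounds overlap in their printed form;
the implementation fixes score ≥ 85 → High-Performance (one 25 min block),
75 ≤ score < 85 → Medium (20 min), below 75 → High-Intensity Training
(5 min active / 5 rest / 5 active). Tier assignment is per assessment
window, carried between sessions. The HRV gate raises the effective ρ\* by
`ease_step` (default 0.05, cap 0.90) whenever HRV falls more than
`drop_fraction` (default 20%) below baseline, and restores the configured
ρ\* on recovery.

## Plasticity substrate

Hopfield: energy `E = −½Σ wᵢⱼsᵢsⱼ + Σ θᵢsᵢ` with the pairwise convention
`−Σ_{i<j} wᵢⱼsᵢsⱼ` as a second accessor (equal when θ = 0, pinned by a
test). Asynchronous sign updates with sign(0) → +1; energy is non-increasing
and every trajectory terminates in a fixed point, which the tests verify
against brute-force enumeration over all 2ⁿ states for n ≤ 10. Reward-driven
"basin deepening" adds `rate·outer(t, t)` (zero diagonal) and provably
lowers the target's energy; basin growth is checked by enumeration at small n.

BCM: the nonlinearity is the classic quadratic `φ = gain·y·(y − θm)` — the
minimal function with the required sign structure (LTD below θm, zero at θm,
LTP above) — and the sliding threshold is the standard quadratic-mean rule
`θm = ⟨y²⟩/y₀`, whose fixed point under constant activity y₀ stabilizes
runaway growth. Both the nonlinearity and the sliding rule were open
choices; alternatives preserving the sign structure would pass the same
tests. STDP uses exponential kernels (τ = 20 ms) with a hard cutoff at
|Δt| = 40 ms and zero contribution at Δt = 0. Homeostatic scaling is the
linear controller `dG/dt = γ(R_target − R)`.

The whole-brain twin is a sigmoidal rate network
`τ·drᵢ/dt = −rᵢ + S(G·Σ Cᵢⱼrⱼ + I)` with `S(u) = 1/(1+exp(−(u−½)/d))`,
Euler-integrated at 1 ms with seeded additive noise (SD 0.01/√ms). Defaults:
76 regions, coupling G = 0.015, gain shape d = 0.3, 2000 ms, τ = 10 ms. The
parameter d shapes the sigmoid steepness; it is named a "Hill coefficient"
in the source material with conflicting glosses, and the sigmoid-gain
reading is implemented. The connectome is a seeded synthetic stand-in
(distance-dependent symmetric weights with log-normal scatter, zero
diagonal, scale-normalized), not an atlas parcellation. Stability is
reported as drift of the network-mean rate over the last quarter of the run
below 10⁻³ per ms; divergence is flagged in the report rather than raised.
No confidence-level statistic is attached to stability — none is defined
for this criterion — the drift tolerance is the operational test.

## Closed loop and the virtual subject

Per epoch (1 s): the subject state renders to per-channel spectral models,
an epoch of EEG is synthesized, y is measured (mean training-band density
on a zero-padded periodogram for enhance protocols — the default band
9.78–10.25 Hz is narrower than the raw 1 Hz epoch resolution — or the
Theta/Alpha ratio for suppress), the controller decides against its current
threshold and then updates, the subject steps, and the HRV gate is applied.
The subject model is a deliberate stand-in — no subject response dynamics
are defined by the framework itself — using the minimal monotone rule:
rewarded epochs move each parameter toward its normative target by
`responsiveness × (target − current)` (i-APF capped at its ceiling,
default 10.25 Hz); unrewarded epochs relax toward the personal baseline at
one fifth that rate. This guarantees i-APF monotonicity under all-rewarded
sequences and makes "CDI subtraction" a consequence of sustained reward
rather than an assumption.

i-APF and CDI are recomputed every 10 epochs on a sliding 30-epoch buffer
(spectral estimates need integration time); the center-of-gravity rule is
applied per posterior channel and averaged. The HRV stream is an AR(1)
process around baseline with optionally scripted drops to exercise the gate.

## Problem sizes and verification fixtures

- Parameter-recovery grid: exponent x ∈ {0.5, 1, 1.5, 2} × peak amplitude
  ∈ {2×, 5×} the local aperiodic level at the peak, 120 s recordings,
  10 seeds per cell; tolerances ±0.15 on x and ±0.25 Hz on centers with a
  ≥95% pass requirement. Amplitude is specified *relative to the local
  background* because recoverability is governed by peak-to-background
  ratio; 2× is a modest but clearly present rhythm, 5× a prominent one. A
  peak well below its background is not reliably localizable in frequency
  at this record length by any estimator — the center's sampling error is
  at the information limit, not the implementation.
- Worked-example fixture: the percent tolerance on the CDI% reproduction
  translates to millihertz precision on the i-APF, so the verification
  recording is long (20 min) with a sharp (σ = 0.5 Hz), prominent (8×
  background) alpha at exactly 9.78 Hz on all 19 channels, analyzed with
  4 s Welch windows.
- Controller set point: 5000 one-second epochs, trailing 2000 scored, both
  ρ\* presets (0.70, 0.85), tolerance ±0.03.
- Hopfield oracle: 100 seeded nets, n ∈ [3, 10]; exhaustive starts for
  n ≤ 7, 40 random starts otherwise.
- Longitudinal program: 16 chained sessions of 2 min at desk scale
  (responsive subject, responsiveness 0.004, vs an unresponsive control);
  the endpoint is median CDI% over the last three sessions below the first
  three, and a trend slope whose 95% CI covers zero for the control.

## Known limitations

- No volume conduction or artifact model in the generator; estimator
  robustness to real artifacts is untested by design.
- The EDF writer targets the plain 16-bit EDF profile (integer sampling
  rates, 1 s records, one physical range per file); it is not a general
  EDF+ implementation. Reading goes through MNE.
- The spherical head model, ROI blocks and synthetic connectome are toys;
  nothing here supports anatomical claims.
- Phase–amplitude coupling metrics, multitaper/wavelet estimators,
  eLORETA/beamformers, realistic BEM/FEM head models and any clinical
  scoring are out of scope.
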