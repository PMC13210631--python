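# Methods

This note documents the model implemented by `ethosim`, the choices made
where the design was genuinely open, what the synthetic fixture world does
and does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` do not themselves
compute.

## 1. Model and assumptions

The package factorizes an observed, labeled planar trajectory into a latent
behavioral process and an additive, sensing-regime-dependent observation
channel:

    z_t → x_t → x̃_t = x_t + e_t ,   c ∈ {LoS, NLoS} constant per session.

Assumptions baked into this factorization:

* three behavioral states (exploring, feeding, burrowing); no resting state;
* behavioral dynamics are semi-Markov at the run level: succession of
  *distinct* states is first-order Markov (zero-diagonal transition matrix),
  persistence is an explicit per-state dwell-time distribution kept fully
  empirical (bootstrap resampling of observed run durations; no parametric
  family is imposed);
* kinematic increments (step length, turning angle) are conditionally
  independent across time given the arrival-state label — no long-range
  motion motifs, no subject-specific style;
* observation distortion is additive, i.i.d. across frames given
  (state, regime), with no temporal autocorrelation, spatial dependence, or
  burst structure;
* sessions are wholly LoS or wholly NLoS; the frame-level regime equals the
  session regime.

### Reference proxy, not ground truth

No external ground-truth track exists in a UWB-only recording, so the
"latent" trajectory used for calibration is a smoothed proxy of the observed
track (centered rolling median then rolling mean). Residuals against this
proxy mix true sensing error with smoother motion-leakage (real motion the
window cannot follow, and run-boundary contamination where a short bout sits
inside the window of a faster neighboring bout). Two consequences are worth
stating explicitly:

* the fitted channel describes *proxy-referenced* distortion, not absolute
  localization error — biases are largely absorbed by the smoother and the
  fitted mixture is heavier-tailed than the true sensing noise;
* realism metrics that compare real and synthetic residuals are internally
  consistent (both sides use the same proxy), so closure tests remain
  meaningful even though neither side is a true error distribution.

## 2. Calibration pipeline and tunables

| parameter | default | units | role |
|---|---|---|---|
| Δt | 0.1 | s | sampling interval (10 Hz) |
| w (LoS / NLoS) | 21 / 41 | samples | smoother window; wider under NLoS because outliers are larger and more frequent |
| grid step | 0.001 | — | exhaustive 1-D search for the exploring-exit calibration α̂ |
| p_ℓ = p_θ | 0.995 | — | Winsorization percentile for latent step/turn caps |
| p_e | 0.999 | — | radial cap percentile for sampled distortions |
| ν | 4 | — | Student-t dof of the outlier component (fixed, not estimated) |
| N_min | 5 | samples | minimum bin size before hierarchical pooling (state+regime → regime → global) |
| B, ε | 50, 1e-12 | — | histogram bins and additive smoothing for KL metrics |
| T | 3000 | frames | default synthetic session length (300 s) |
| max MSD lag | 30 | s | lag grid k = 1..300 |

Only the exploring-exit row is calibrated because exploring dominates the
frame budget through long dwells while producing few run-level exits; its
maximum-likelihood row is therefore the noisiest quantity with the largest
leverage on induced occupancy. The two rare-state rows keep their empirical
(renormalized) estimates.

### Numerical choices

* **Stationary distribution**: exact left-eigenvector of the 3×3 chain
  (validated against power iteration in the tests); the eigenvalue-1 space
  must be one-dimensional, otherwise the chain is rejected as reducible.
  Residual tolerance ‖μᵀP − μᵀ‖∞ < 1e-10.
* **Smoother boundaries**: centered windows shrink symmetrically (down to a
  single sample) so every frame has a reference and no NaN ever enters the
  residual set.
* **Quantiles**: type-7 (linear interpolation between order statistics)
  everywhere, for reproducibility.
* **Angle wrap**: (−π, π], with wrap(θ + 2πk) = wrap(θ) exactly.
* **Channel EM**: the Student-t is handled by Gamma scale-mixture
  augmentation; updates are ECM-style (shared location given old shapes,
  then shapes and mixing weight), which preserves monotone observed-data
  log-likelihood (asserted within 1e-9 relative slack in the tests).
  Initialization: μ = sample mean, Σ = Λ = sample covariance, ρ = 0.05.
  Stopping: relative log-likelihood change < 1e-8 or 200 iterations.
  Diagonal regularization 1e-9 m² on Σ and Λ; ρ clipped to
  [1e-4, 1 − 1e-4] to prevent component death.
* **Feeding smoothing**: singleton-run decisions are evaluated on the
  original run structure, then the sequence is rebuilt; ties between equal
  neighbor runs go to the preceding run. Boundary singletons (first/last
  run) are left untouched because they lack a two-sided neighborhood.
* **Synthesis determinism**: one `numpy` Generator per session, consumed in
  a fixed order (state sequence, initial heading, steps, turns, distortions,
  each grouped by state in id order); session i of a cohort uses
  seed base + i. Fixed seeds reproduce sessions bit-for-bit.
* **Final-run truncation**: state sequences land exactly on T frames by
  truncating the last dwell draw (rejection would bias long dwells away from
  the sequence end).

### Open choices resolved by this package

* Run dynamics, occupancy calibration and kinematic priors pool LoS and
  NLoS sessions (they describe behavior, which the regime should not
  change); per-regime estimation is available via `RunConfig(pool_regimes=
  False)` as a flag but is not the default. The observation channel is
  always per-regime.
* The first run's state is drawn from the stationary *run* distribution
  μ(α̂) (the run-level object initiates runs), not from the frame occupancy.
* Initial position defaults to the arena origin; the initial heading is
  uniform on (−π, π] to avoid directional bias.
* Distortion caps follow the same pooling chain as the channel parameters
  when a bin is sparse.
* A turn is sampled for every step including the first (φ_2 = φ_1 + θ_2),
  matching the propagation recursion.

## 3. The fixture world

`ethosim.fixtures` generates "real-like" sessions from a fully known ground
truth so every stage is testable without the original recordings. The
defaults emulate a mouse in an open arena at 10 Hz:

* exploring-dominant chain (exits 0.60/0.40 to feeding/burrowing) with mean
  bouts of 15 s exploring, 2.5 s feeding, 5 s burrowing (shifted
  negative-binomial dwells, heavy-ish tails);
* gamma step laws with means 0.20 / 0.04 / 0.08 m s⁻¹ and wrapped-normal
  turn laws (σ = 0.35 / 1.2 / 0.8 rad) for exploring / feeding / burrowing;
* LoS channel: ~1 cm bias, 2 cm nominal sd, 2–4% outliers; NLoS channel:
  ~6 cm bias, 4 cm nominal sd, 12–18% Student-t(4) outliers at 10 cm scale.

The fixture world matches the model family exactly (semi-Markov states,
conditionally independent increments, i.i.d. additive distortion). A green
closure test therefore establishes that calibration and synthesis are
mutually consistent and recover known parameters — it does **not**
establish that real rodent behavior satisfies those assumptions, nor does
it validate against the real UWB recordings (whose MSD-RMSE comparison
requires the original data deposit and is out of desk scope here).

Because positions are unbounded (no arena walls are modeled), sessions stay
within a few meters of the origin only by virtue of cm-scale steps; very
long syntheses will drift.

## 4. Domain-shift benchmark

The perturbed class applies, per session: one speed factor u ~ U(0.02, 0.12)
rescaling latent displacements (distortion re-added unchanged), one relabel
fraction f ~ U(0.003, 0.012) flipping uniformly chosen exploring frames to
feeding, and i.i.d. Gaussian jitter with sd ~ U(1, 6) mm on the observed
track. Feeding smoothing is *not* re-applied after relabeling (perturbation
acts on finished sessions). Session features: occupancy (3), observed step
statistics (mean/sd/median/p95), |turn| statistics (mean/sd),
proxy-residual magnitude statistics (mean/sd/p99), observed MSD at lags
1/5/10 s, plus a 0/1 regime indicator in the sensor-aware settings.
Classifier: L2 logistic regression (C = 1) on features z-scored by training
statistics; thresholded metrics use the fixed 0.5 cutoff. Cohorts are 600
sessions (300 per class), split 300/300 into train/test with disjoint seed
blocks; mixed-domain settings use a 50/50 LoS/NLoS composition with
identical regime composition in both classes.

In this package's fixture world the sensor-aware mixed-domain AUC and the
threshold-collapse failure mode of condition-agnostic transfer (balanced
accuracy at chance in one direction while AUC stays high) reproduce; which
*direction* of transfer degrades most depends on how large sensing
distortion is relative to behavioral motion, and the fixture's long-lag MSD
features remain informative under both regimes, so cross-domain AUC
degrades less than for the real-calibrated model. The acceptance suite
computes and reports these quantities rather than asserting them away.

## 5. Limitations

* Proxy-referenced channel: fitted ρ, Σ, Λ describe residuals against the
  smoothed proxy and overstate tail mass relative to true sensing error.
* No temporal structure in increments or distortion beyond the state
  sequence; no arena boundaries or obstacles.
* Empirical dwell/step/turn priors cannot extrapolate beyond observed
  support; a state never observed in the calibration data aborts
  calibration rather than silently pooling.
* Three states only; resting/immobility is out of scope.
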