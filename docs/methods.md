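# Methods

## Scope and model

`ddsbci` simulates closed-loop iBCI cursor control at the 50 ms bin level.
The loop order each bin is: simulated user intent → synthetic cortex rates
→ decoder velocity command → forward-Euler position update (clipped to the
workspace). Decoders never set position directly; the displayed position is
always the integral of their commands. The Kalman decoders keep an internal
five-element state [pₓ, p_y, vₓ, v_y, 1]; its position entries are synced
to the displayed (integrated, clipped) position each bin, since that is
what a subject sees.

## Synthetic cortex

The neural source is a population of cosine-tuned channels: channel i has a
baseline b_i ~ U(5, 25) Hz, a modulation depth d_i ~ U(5, 20) Hz per
a.u./s, and a preferred direction uniform on the circle; its mean rate for
intent v is max(0, b_i + d_i (v · pd_i)). With noise on, the emitted rate
is a Poisson count over the 50 ms bin divided by the bin width, matching
binned spike-count statistics. Channel counts cycle 71, 45, 70, 82 across
visits, forcing recalibration each visit. A `speed_gain` knob (default 1,
i.e. off) attenuates the speed-modulated component of the tuning, for
studying decoders under weak speed representation.

What this generator does *not* emulate: learning or adaptation by the
user, non-Poisson spiking statistics, correlated channel noise,
nonstationarity within a visit, or the black-box nonlinearity of a real
encoder. Consequently the simulated user is far more proficient than a
naïve human: under the default conditions every decoder reaches ceiling
(100% of 64 targets), and absolute success rates are not comparable to
human or monkey values. Orderings and stopping behaviour remain
informative: DDS shows markedly lower dial-in time than WF under matched
conditions, consistent with the stopping advantage that motivates
discrete selection.

## Simulated user

Intent is a unit vector to the target center scaled by `peak_speed`
(default 1.0 a.u./s, commensurate with the fast DDS menu speed), plus
isotropic Gaussian intent noise (s.d. 0.1 a.u./s), delayed by a 4-bin
(200 ms) visuomotor reaction time; inside the target the intent is zero.
During calibration the user tracks the training cursor's instantaneous
minimum-jerk velocity without the reaction delay — the training trajectory
is fully predictable, so anticipatory tracking is the realistic choice.

## Calibration protocol

Blocks of 8 trials (4 cardinal targets × 2, in sequence); training cursor
on a 1.2 s minimum-jerk path (quintic profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, 24
bins per trial); decoder refit after every block on all prior non-outlier
trials; decoded cursor hidden in blocks 1–2 and closed-loop from block 3
(DR-A blending α = 0.8, 0.6, 0.4, 0.2, 0 over blocks 3–7, 0 afterwards).
Seven blocks by default, extended one at a time (at most two) until every
target has ≥ 4 non-outlier trials; otherwise a protocol failure is raised.
Simulated timing-violation trials are discarded and repeated.

Outlier flagging unrolls each trial's rate matrix through time (trials
resampled to the modal bin count — the temporal alignment is a design
choice), projects all trials onto the top six principal components of the
trial-by-feature matrix (per-visit global PCA), clips pairwise Euclidean
distances at their 90th percentile, and silhouette-scores each trial
against its target cluster; negative scores are flagged. A mid-protocol
refit that fails because a target transiently lost all clean trials keeps
the previous block's model; the final fit is guaranteed by the
four-per-target rule.

## Decoder fitting choices

- vKF: A and H by ordinary least squares (the constant-1 state row is
  pinned to map 1 → 1); Q, R are residual covariances; the gain recursion
  runs to a 1e-12 fixed point and is frozen. Rank-deficient A/H regressors
  raise an error naming the block.
- ReFIT: position rows of A are exact kinematics (p += dt·v); per-axis
  velocity damping is a scalar least-squares fit on intention-relabeled
  velocities; trials with a visible decoded cursor are relabeled from
  their executed closed-loop states, earlier trials from training states.
  Position rows/columns of the error covariance are zeroed before every
  gain computation.
- DR-A / WF: minimum-norm least squares. No rank check: noiseless rates
  driven by 2-D velocity are legitimately rank-deficient, and the
  minimum-norm solution is the standard resolution. WF history is τ+1 = 9
  bins including the current one (400 ms at 50 ms bins); the history
  buffer zero-pads at trial starts and never crosses trial boundaries.
- DDS: trial fifths are labeled stop / slow / fast / slow / slow (remainder
  bins assigned to earlier fifths); the multinomial logit is fit by
  scikit-learn's LBFGS solver with a ridge penalty of 1e-4 on the mean
  log-likelihood (C = 1/(ridge·n)) and tolerance 1e-6 — any optimizer
  reaching that tolerance is acceptable. The mixing norm in
  ξ = Σ v(i) w(i)/‖w‖ is L1: only sum-normalization makes γ = 1 reduce
  exactly to the probability-weighted average. When every weight is zero
  (possible, since a uniform 1/9 lies below 1 − γ = 0.15) the argmax-
  probability menu velocity is emitted; a stop fallback is available by
  configuration. Note the γ-dependence of a weight is not monotone: on the
  linear region dw/dγ ∝ (1 − 2p), so raising γ shrinks confident weights
  and grows unconfident ones.

## Metrics

Tortuosity uses the Menger (circumradius) curvature of consecutive sample
triples, central finite differences for dκ/dt, and trapezoidal
integration over the window 0.25–3 s, normalized by the windowed
pathlength. Straight lines and uniform circular arcs score zero to
numerical precision; the measure is rigid-motion invariant and scales as
1/length² under spatial scaling; a stationary trajectory returns 0 with a
warning. Dial-in time on timeout trials counts raw 2-radius occupancy
(there is no completed hold to subtract). Heading-toward-target excludes
zero-speed bins from numerator and denominator (their heading is
undefined) and discards the leading bins still inside the previous home
target. The discrete Fréchet distance is the standard dynamic program with
Euclidean ground distance and is used unclipped (clipping belongs only to
the calibration outlier silhouette).

## Problem sizes and determinism

One RNG stream per concern (neuron set, schedule, encoder noise, user
noise), all derived from named seeds, so any run is bit-reproducible from
its config. The acceptance script runs the full study conditions: a
complete 7-block calibration, a 10-seed A/B comparison at 64 peripheral
targets per session with Poisson noise, 1000-instance decoder-identity
checks, and brute-force Fréchet enumeration on sequences up to length 6.
The center target has no subject-facing timeout; the simulator
force-recenters after 30 s so a degenerate decoder cannot stall a session,
and sessions also carry the 150 min overall cap.

## Known limitations

Absolute performance does not transfer to humans or animals (see above);
the typing task is scored but not simulated closed-loop; the keyboard
scoring formula is implemented as printed, S = 100·(LD − c)/c, which
scores perfect typing at −100 — an accuracy-oriented sign convention is
available via a switch but is not the default; ReFIT damping details
beyond scalar per-axis least squares are not modeled; no unscented Kalman
filter or neural-network decoders.
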