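# ddsbci

A closed-loop intracortical brain–computer interface (iBCI) cursor-control
simulation toolkit built around the **discrete direction selection (DDS)**
decoder and four continuous-velocity comparators: the velocity Kalman
filter (vKF), ReFIT, direct regression with assist (DR-A), and the Wiener
filter (WF). It is aimed at neural-engineering researchers who want to
prototype and compare cursor decoders — calibration protocol included —
without a subject in the loop.

## What it simulates

Every decoder consumes one 50 ms bin of firing rates **z** (c channels) and
emits a 2-D velocity command; cursor position is the Euler integral of
those commands, clipped to a square workspace of side 2 a.u. Circular
targets of radius 0.15 a.u. sit 0.85 a.u. from the origin; a *hit* requires
the cursor center to stay inside a target continuously for the 0.5 s hold
(20 s timeout per peripheral target, 8 targets × 8 occurrences).

The decoders:

- **vKF** — constant-gain Kalman filter on x = [pₓ, p_y, vₓ, v_y, 1]ᵀ:
  xₜ = A xₜ₋₁ + K (zₜ − H A xₜ₋₁); A, H by least squares on calibration
  states, K iterated to the steady-state gain and frozen.
- **ReFIT** — same update, with a damped-kinematics A, H fit on
  intention-relabeled states (velocity rotated toward the target, zeroed
  inside it), and position uncertainty zeroed in the gain recursion.
- **DR-A** — affine map xₜ = B zₜ fit on bins with training-cursor speed
  ≥ 0.03 a.u./s; during calibration the command is blended with the
  training velocity, xₜ = α xₜᵗʳᵃⁱⁿ + (1 − α) B zₜ, α stepping
  0.8 → 0 across blocks.
- **WF** — the same affine map on τ+1 = 9 bins (400 ms) of rate history.
- **DDS** — a multinomial logit over η = 9 menu velocities (fast 1.0 and
  slow 0.5 a.u./s in each cardinal direction, plus stop). Probabilities
  pass through the piecewise-linear weighting
  w(i) = clip((pₜ(i) + γ − 1)/(2γ − 1), 0, 1), γ = 0.85, and the command is
  the weight-averaged menu velocity ξ = Σ v(i)·w(i)/‖w‖₁.

Since there is no subject, a **synthetic cortex** closes the loop: each
channel is cosine-tuned to intended velocity
(rate = max(0, b + d·(intent·pd))) with Poisson count noise per 50 ms bin,
and a simulated user with reaction delay and intent noise chases the
targets. Per-visit neuron turnover cycles the channel count through
71, 45, 70, 82. Calibration shows a 1.2 s minimum-jerk training cursor to
four cardinal targets in blocks of 8 trials, refits the decoder after
every block, and flags outlier trials by silhouette scoring in a 6-D
PCA-through-time latent space (pairwise distances clipped at their 90th
percentile).

Analysis metrics: targets hit, time-to-target histograms, speed at hit,
dial-in time (time within 2 radii, final hold excluded), heading-toward-
target fraction, tortuosity T = (1/L)∫|dκ/dt| dt, DDS selection-mixing
grids, discrete Fréchet distance, offline decode-vs-training similarity,
and neural-trajectory separability in PC space.

## Worked example

```sh
ddsbci run-session --decoder dds --seed 0 --out session0
```

calibrates a DDS decoder on the visit-1 synthetic population (71 channels)
and runs the 64-target center-out task. Output printed by the run:

```
{
 "n_peripheral": 64,
 "n_hits": 64,
 "success_rate": 100.0,
 "mean_time_to_target": 2.2093749999999988,
 "mean_dial_in_time": 0.32265625000000003,
 "mean_speed_at_hit": 0.22946405447575619
}
```

All 64 peripheral targets were hit; the mean reach took ≈2.2 s and the
cursor spent ≈0.32 s "dialing in" near the target before the hold. The
simulated user is far more proficient than a naïve human subject, so
success rates sit at ceiling for every decoder; *orderings* between
decoders (e.g. DDS stops faster than WF) are the meaningful comparisons.
The same library surface is available in Python:

```python
from ddsbci.cli_io import ExperimentConfig, run_experiment
res = run_experiment(ExperimentConfig(decoder="dds", session_seed=0))
print(res.summary)
```

`ddsbci ab-compare` runs matched-seed A/B sessions across decoders, and
`ddsbci analyze --session session0` recomputes the per-trial metrics from
a stored log.

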