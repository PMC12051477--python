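"""Synthetic motor-cortex firing-rate source and simulated user.

Stands in for a recorded (or emulated) neural population: each channel is a
cosine-tuned unit whose mean rate is an affine function of the intended 2-D
cursor velocity,

    rate_i = max(0, baseline_i + depth_i * (intent . pd_i)),

with optional Poisson count noise over the 50 ms bin. Per-"visit" neuron
turnover is modeled by drawing a fresh tuned population each visit, cycling
through the fixed set sizes (71, 45, 70, 82) so that every visit forces a
decoder recalibration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

#: Channel counts for visits 1..4 (then cycling).
VISIT_SET_SIZES = (71, 45, 70, 82)

BIN_WIDTH_S = 0.05


@dataclass
class NeuronSet:
    """One visit's emulated population: per-channel tuning parameters."""

    visit: int
    baseline: np.ndarray  # (c,) Hz
    depth: np.ndarray  # (c,) Hz per a.u./s
    preferred_direction: np.ndarray  # (c, 2) unit vectors
    #: scales the speed-modulated part of the tuning; 1.0 = full speed
    #: information, < 1 attenuates it (speed may be weakly represented in
    #: real populations).
    speed_gain: float = 1.0
    #: session-level noise switch; ``encode`` without an explicit ``noise``
    #: argument follows it, so a noiseless encoder is just ``noisy=False``.
    noisy: bool = True

    @property
    def n_channels(self) -> int:
        return self.baseline.shape[0]

    def encode(self, intent, noise: bool | None = None, rng=None) -> np.ndarray:
        return encode(intent, self, noise=self.noisy if noise is None else noise, rng=rng)

    def to_dict(self) -> dict:
        return {
            "visit": self.visit,
            "baseline": self.baseline.tolist(),
            "depth": self.depth.tolist(),
            "preferred_direction": self.preferred_direction.tolist(),
            "speed_gain": self.speed_gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronSet":
        return cls(
            visit=int(d["visit"]),
            baseline=np.asarray(d["baseline"], dtype=float),
            depth=np.asarray(d["depth"], dtype=float),
            preferred_direction=np.asarray(d["preferred_direction"], dtype=float),
            speed_gain=float(d.get("speed_gain", 1.0)),
        )


def make_neuron_set(visit: int, seed, speed_gain: float = 1.0) -> NeuronSet:
    """Draw the tuned population for a visit.

    The channel count is the ``(visit-1) mod 4``-th entry of
    ``VISIT_SET_SIZES``; preferred directions are uniform on the circle,
    baselines uniform on [5, 25] Hz and modulation depths uniform on
    [5, 20] Hz per unit speed. The draw is a pure function of
    ``(visit, seed)``.
    """
    if visit < 1:
        raise ValueError("visit index starts at 1")
    c = VISIT_SET_SIZES[(visit - 1) % len(VISIT_SET_SIZES)]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(visit,)))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=c)
    pd = np.column_stack([np.cos(theta), np.sin(theta)])
    baseline = rng.uniform(5.0, 25.0, size=c)
    depth = rng.uniform(5.0, 20.0, size=c)
    return NeuronSet(visit=visit, baseline=baseline, depth=depth,
                     preferred_direction=pd, speed_gain=speed_gain)


def encode(intent, neurons: NeuronSet, noise: bool = True, rng=None) -> np.ndarray:
    """One 50 ms bin of firing rates (Hz) for an intended velocity.

    Noiseless: the rectified cosine-tuned mean rate, deterministically.
    With noise: a Poisson spike count over the bin divided by the bin
    width, so the returned rate has the mean of the noiseless rate and
    Poisson count statistics.
    """
    intent = np.asarray(intent, dtype=float)
    if not np.all(np.isfinite(intent)):
        raise ValueError("non-finite intent")
    drive = neurons.depth * (neurons.preferred_direction @ intent) * neurons.speed_gain
    mean = np.maximum(0.0, neurons.baseline + drive)
    if not noise:
        return mean
    rng = np.random.default_rng() if rng is None else rng
    counts = rng.poisson(mean * BIN_WIDTH_S)
    return counts / BIN_WIDTH_S


@dataclass
class UserPolicyConfig:
    """Simulated-subject parameters.

    reaction_delay_bins: visuomotor latency between seeing the cursor/target
    state and the intent that responds to it (default 4 bins = 200 ms).
    peak_speed: intended reach speed in a.u./s.
    intent_noise_sd: isotropic Gaussian jitter added to the intent, a.u./s.
    """

    reaction_delay_bins: int = 4
    peak_speed: float = 1.0
    intent_noise_sd: float = 0.1

    def __post_init__(self):
        if self.reaction_delay_bins < 0:
            raise ValueError("delays must be >= 0")


def user_intent(cursor_pos, target, phase: str, policy: UserPolicyConfig, rng=None):
    """Noiseless-core intent for one bin, before reaction delay.

    ``calibration_follow`` passes through the training cursor's velocity
    (supplied as ``target`` in that phase); ``reach`` aims at the target
    center at peak speed; ``hold`` is zero intent. Gaussian intent noise is
    added when an rng is given.
    """
    if phase == "calibration_follow":
        base = np.asarray(target, dtype=float)
    elif phase == "reach":
        d = np.asarray(target.center, dtype=float) - np.asarray(cursor_pos, dtype=float)
        dist = np.hypot(d[0], d[1])
        base = np.zeros(2) if dist == 0 else policy.peak_speed * d / dist
    elif phase == "hold":
        base = np.zeros(2)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if rng is not None and policy.intent_noise_sd > 0:
        base = base + rng.normal(0.0, policy.intent_noise_sd, size=2)
    return base


class SimulatedUser:
    """Stateful wrapper applying the reaction delay to the intent policy.

    The intent emitted at bin t is the noiseless policy evaluated on the
    cursor/target state observed at bin t - d (d = reaction delay), plus
    fresh intent noise.
    """

    def __init__(self, policy: UserPolicyConfig | None = None):
        self.policy = policy or UserPolicyConfig()
        self._buffer: deque = deque()

    @property
    def n_delay(self) -> int:
        return self.policy.reaction_delay_bins

    def reset(self):
        self._buffer.clear()

    def step(self, cursor_pos, target, rng=None) -> np.ndarray:
        phase = "hold" if target.contains(cursor_pos) else "reach"
        self._buffer.append((tuple(cursor_pos), target, phase))
        if len(self._buffer) <= self.n_delay:
            # before the first observation propagates, intend nothing
            base = np.zeros(2)
            if rng is not None and self.policy.intent_noise_sd > 0:
                base = base + rng.normal(0.0, self.policy.intent_noise_sd, size=2)
            return base
        pos_d, target_d, phase_d = self._buffer.popleft()
        return user_intent(pos_d, target_d, phase_d, self.policy, rng=rng)
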