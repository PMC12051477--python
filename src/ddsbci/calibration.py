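"""Four-target calibration protocol and training-dataset construction.

Calibration shows a training cursor that travels from the workspace center
to one of four cardinal targets along a 1.2 s minimum-jerk path; the
simulated user tracks it while the synthetic cortex emits rates. The four
targets are presented in sequence and the sequence repeated twice (one
block of 8 trials); after every block the decoder is refit on all prior
non-outlier data. The decoded cursor is hidden in blocks 1-2 and shown
from block 3, where DR-A's assist blends it with the training velocity on
the schedule alpha = 0.8, 0.6, 0.4, 0.2, 0 over blocks 3-7 (0 afterwards).
Seven blocks are run by default, extended one at a time (at most two) until
every target has at least four non-outlier trials.

Outlier trials are flagged by unrolling each trial's rate matrix through
time, projecting all trials into a 6-D PCA latent space, clipping pairwise
distances at their 90th percentile, and silhouette-scoring each trial
against its calibration-target cluster: a negative score flags the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from ddsbci import decoders as _dec
from ddsbci.synthetic_cortex import UserPolicyConfig, user_intent
from ddsbci.task_engine import CursorState, Target, clip_to_workspace

CALIBRATION_DURATION = 1.2  # s, minimum-jerk transit time
CALIBRATION_BIN_DT = 0.05
N_CALIBRATION_TARGETS = 4
MIN_CLEAN_PER_TARGET = 4
DEFAULT_BLOCKS = 7
MAX_EXTRA_BLOCKS = 2

#: Calibration targets: East, North, West, South at 0.85 a.u., radius 0.15.
CARDINAL_DIRECTIONS = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
CARDINAL_NAMES = ("E", "N", "W", "S")


def cardinal_targets(distance: float = 0.85, radius: float = 0.15) -> list[Target]:
    return [
        Target(center=(distance * d[0], distance * d[1]), radius=radius, label=n)
        for d, n in zip(CARDINAL_DIRECTIONS, CARDINAL_NAMES)
    ]


class ProtocolFailure(RuntimeError):
    """Raised when calibration cannot reach four clean trials per target."""


def minimum_jerk(start, end, duration: float, t: float) -> CursorState:
    """Minimum-jerk state at time t on the straight segment start -> end.

    The normalized position profile is the quintic
    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 (tau = t/duration), whose
    derivative gives the velocity; both endpoint velocities are zero.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= t <= duration + 1e-12:
        raise ValueError(f"t={t} outside [0, {duration}]")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    tau = min(t / duration, 1.0)
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5
    ds = (30.0 * tau**2 - 60.0 * tau**3 + 30.0 * tau**4) / duration
    pos = start + s * (end - start)
    vel = ds * (end - start)
    return CursorState(px=pos[0], py=pos[1], vx=vel[0], vy=vel[1])


@dataclass
class CalibrationTrial:
    """One tracked center-to-target transition."""

    target_index: int  # 0..3 into CARDINAL_DIRECTIONS
    block: int  # 1-based
    rates: np.ndarray  # (n_bins, c)
    train_pos: np.ndarray  # (n_bins, 2)
    train_vel: np.ndarray  # (n_bins, 2)
    decoded_pos: np.ndarray | None = None  # closed-loop, blocks >= 3
    decoded_vel: np.ndarray | None = None
    target: Target | None = None

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def direction(self) -> np.ndarray:
        return CARDINAL_DIRECTIONS[self.target_index]


@dataclass
class OutlierReport:
    projection: np.ndarray  # (n_trials, 6)
    scores: np.ndarray  # silhouette per trial
    flags: np.ndarray  # bool, True = outlier


def flag_outliers(trials: list[CalibrationTrial], n_components: int = 6,
                  clip_percentile: float = 90.0) -> OutlierReport:
    """Silhouette-based outlier flagging in a PCA-through-time latent space.

    Each trial's rate matrix is unrolled through time (trials resampled to
    the modal bin count), all trials are projected onto the top principal
    components, pairwise Euclidean distances are clipped at their
    ``clip_percentile`` so extreme trials cannot distort the clusters, and
    each trial is silhouette-scored against its target cluster. Scores
    below zero are flagged.
    """
    labels = np.array([t.target_index for t in trials])
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 calibration targets represented")
    counts = np.bincount(labels, minlength=N_CALIBRATION_TARGETS)
    if np.any((counts > 0) & (counts < 2)):
        raise ValueError("need at least 2 trials per represented target")
    lengths = [t.n_bins for t in trials]
    modal = int(np.bincount(lengths).argmax())
    if modal < 2:
        raise ValueError("trials too short to project through time")

    feats = []
    for t in trials:
        r = t.rates
        if r.shape[0] != modal:
            xs = np.linspace(0.0, 1.0, modal)
            xp = np.linspace(0.0, 1.0, r.shape[0])
            r = np.column_stack([np.interp(xs, xp, r[:, j]) for j in range(r.shape[1])])
        feats.append(r.reshape(-1))
    F = np.asarray(feats)
    k = min(n_components, F.shape[0], F.shape[1])
    proj = PCA(n_components=k).fit_transform(F)
    d = pdist(proj)
    clip = np.percentile(d, clip_percentile)
    D = squareform(np.minimum(d, clip))
    scores = silhouette_samples(D, labels, metric="precomputed")
    return OutlierReport(projection=proj, scores=scores, flags=scores < 0.0)


def label_fifths(trial: CalibrationTrial) -> np.ndarray:
    """Per-bin DDS selection labels by the trial-fifths rule.

    Bins are split by time into five contiguous fifths (remainder bins go
    to the earlier fifths): the first fifth is 'stop', the middle fifth is
    'fast' (1 a.u./s) toward the trial's target, and fifths two, four and
    five are 'slow' (0.5 a.u./s) toward the target.
    """
    n = trial.n_bins
    if n < 5:
        raise ValueError("trial must have at least 5 bins")
    d = trial.direction
    fast = _menu_index(d)
    slow = _menu_index(0.5 * d)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    per_fifth = [_dec.STOP_INDEX, slow, fast, slow, slow]
    labels = np.concatenate([np.full(s, lab) for s, lab in zip(sizes, per_fifth)])
    return labels.astype(int)


def _menu_index(v) -> int:
    hits = np.flatnonzero(np.all(np.isclose(_dec.MENU, np.asarray(v, dtype=float)), axis=1))
    if hits.size != 1:
        raise ValueError(f"velocity {v} is not a menu selection")
    return int(hits[0])


def relabel_intention(positions, velocities, target: Target) -> np.ndarray:
    """Intention relabeling: rotate each out-of-target velocity to point
    from the cursor position to the target center (speed preserved); zero
    velocity inside the target. Positions are kept as executed."""
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    out = np.zeros_like(velocities)
    c = np.asarray(target.center, dtype=float)
    for i, (pos, vel) in enumerate(zip(positions, velocities)):
        if target.contains(pos):
            continue
        d = c - pos
        dist = math.hypot(d[0], d[1])
        speed = math.hypot(vel[0], vel[1])
        if dist > 0:
            out[i] = speed * d / dist
    return out


def blend_assist(alpha: float, train_velocity, decoded_velocity) -> np.ndarray:
    """Assisted calibration: x_t = alpha * x_train + (1 - alpha) * B z_t."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * np.asarray(train_velocity, dtype=float) + (1.0 - alpha) * np.asarray(
        decoded_velocity, dtype=float
    )


def assist_alpha(block: int) -> float:
    """Assist level per block: decoded cursor hidden before block 3 (1.0),
    then 0.8 decreasing by 0.2 to 0 across blocks 3-7, and 0 afterwards."""
    if block < 3:
        return 1.0
    schedule = (0.8, 0.6, 0.4, 0.2)
    return schedule[block - 3] if block - 3 < len(schedule) else 0.0


@dataclass
class CalibrationDataset:
    """Labeled, outlier-flagged calibration trials plus fit helpers.

    All ``*_matrix`` accessors exclude flagged outlier trials.
    """

    trials: list[CalibrationTrial] = field(default_factory=list)
    outlier_flags: np.ndarray | None = None
    outlier_report: OutlierReport | None = None
    bin_dt: float = CALIBRATION_BIN_DT
    decoder_kind: str | None = None
    n_blocks: int = 0
    n_discarded: int = 0
    targets: list[Target] = field(default_factory=cardinal_targets)
    fitted_model: object | None = None

    def clean_trials(self) -> list[CalibrationTrial]:
        if self.outlier_flags is None:
            return list(self.trials)
        return [t for t, f in zip(self.trials, self.outlier_flags) if not f]

    def clean_counts(self) -> np.ndarray:
        counts = np.zeros(N_CALIBRATION_TARGETS, dtype=int)
        for t in self.clean_trials():
            counts[t.target_index] += 1
        return counts

    # ---- fit helpers (training-cursor "reference" states) ----

    def _train_states(self, trial: CalibrationTrial) -> np.ndarray:
        n = trial.n_bins
        return np.column_stack(
            [trial.train_pos, trial.train_vel, np.ones(n)]
        )

    def state_matrix(self) -> np.ndarray:
        return np.vstack([self._train_states(t) for t in self.clean_trials()])

    def rate_matrix(self) -> np.ndarray:
        return np.vstack([t.rates for t in self.clean_trials()])

    def state_transition_pairs(self):
        prev, nxt = [], []
        for t in self.clean_trials():
            s = self._train_states(t)
            prev.append(s[:-1])
            nxt.append(s[1:])
        return np.vstack(prev), np.vstack(nxt)

    def trial_arrays(self):
        """(rates, states) per clean trial, for history-aware fits."""
        return [(t.rates, self._train_states(t)) for t in self.clean_trials()]

    def refit_states(self) -> list[np.ndarray]:
        """Intention-relabeled states per clean trial.

        Trials with a closed-loop decoded cursor (blocks with the decoded
        cursor visible) are relabeled from their executed decoded states;
        earlier trials fall back to the training-cursor states.
        """
        out = []
        for t in self.clean_trials():
            if t.decoded_pos is not None:
                pos, vel = t.decoded_pos, t.decoded_vel
            else:
                pos, vel = t.train_pos, t.train_vel
            target = t.target or cardinal_targets()[t.target_index]
            v2 = relabel_intention(pos, vel, target)
            out.append(np.column_stack([pos, v2, np.ones(len(pos))]))
        return out

    def dds_labels(self) -> np.ndarray:
        return np.concatenate([label_fifths(t) for t in self.clean_trials()])


def run_calibration(
    decoder_kind: str | None,
    encoder,
    user_policy: UserPolicyConfig | None = None,
    seed=0,
    n_blocks: int = DEFAULT_BLOCKS,
    max_extra_blocks: int = MAX_EXTRA_BLOCKS,
    timing_violation_prob: float = 0.0,
    decoder_hyper: dict | None = None,
) -> CalibrationDataset:
    """Run the full block-structured calibration and return the dataset.

    After every block the decoder (if any) is refit on all prior
    non-outlier trials; from block 3 the decoded cursor runs closed-loop on
    the emitted rates (DR-A blending its output with the training velocity
    on the assist schedule). Blocks are appended one at a time beyond
    ``n_blocks`` (at most ``max_extra_blocks``) until every target has at
    least four non-outlier trials; failing that raises ProtocolFailure.
    Trials simulating a subject timing violation are discarded and repeated.
    """
    policy = user_policy or UserPolicyConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    targets = cardinal_targets()
    n_bins = int(round(CALIBRATION_DURATION / CALIBRATION_BIN_DT))
    dataset = CalibrationDataset(decoder_kind=decoder_kind)
    runner = None
    model = None
    block = 0
    while True:
        block += 1
        alpha = assist_alpha(block)
        for rep in range(2):
            for ti, target in enumerate(targets):
                while True:  # repeat on timing violation
                    trial = _run_trial(
                        ti, target, block, n_bins, encoder, policy, rng,
                        runner, alpha, dataset.bin_dt,
                    )
                    if timing_violation_prob > 0 and rng.random() < timing_violation_prob:
                        dataset.n_discarded += 1
                        continue
                    break
                dataset.trials.append(trial)
        report = flag_outliers(dataset.trials)
        dataset.outlier_report = report
        dataset.outlier_flags = report.flags
        dataset.n_blocks = block
        if decoder_kind is not None:
            try:
                model = _dec.fit_decoder(decoder_kind, dataset, **(decoder_hyper or {}))
                runner = _dec.make_decoder(decoder_kind, model)
            except (ValueError, np.linalg.LinAlgError):
                # a target can transiently lose all its clean trials early
                # in the protocol; keep the previous block's model until
                # enough clean data accumulates
                pass
        if block >= n_blocks:
            if np.all(dataset.clean_counts() >= MIN_CLEAN_PER_TARGET):
                break
            if block >= n_blocks + max_extra_blocks:
                raise ProtocolFailure(
                    f"fewer than {MIN_CLEAN_PER_TARGET} clean trials per target "
                    f"after {block} blocks (counts {dataset.clean_counts().tolist()})"
                )
    if decoder_kind is not None:
        # final fit on the completed dataset (>= 4 clean trials per target)
        model = _dec.fit_decoder(decoder_kind, dataset, **(decoder_hyper or {}))
    dataset.fitted_model = model
    return dataset


def _run_trial(target_index, target, block, n_bins, encoder, policy, rng,
               runner, alpha, dt) -> CalibrationTrial:
    start = np.zeros(2)
    end = np.asarray(target.center, dtype=float)
    rates = np.empty((n_bins, encoder.n_channels))
    train_pos = np.empty((n_bins, 2))
    train_vel = np.empty((n_bins, 2))
    decoded = runner is not None and block >= 3
    dec_pos = np.empty((n_bins, 2)) if decoded else None
    dec_vel = np.empty((n_bins, 2)) if decoded else None
    if decoded:
        runner.reset((0.0, 0.0))
        cur = (0.0, 0.0)
    for i in range(n_bins):
        t = (i + 1) * dt
        st = minimum_jerk(start, end, CALIBRATION_DURATION, min(t, CALIBRATION_DURATION))
        train_pos[i] = (st.px, st.py)
        train_vel[i] = (st.vx, st.vy)
        intent = user_intent(None, (st.vx, st.vy), "calibration_follow", policy, rng=rng)
        z = encoder.encode(intent, rng=rng)
        rates[i] = z
        if decoded:
            v, _aux = runner.step(z, cur)
            v = blend_assist(alpha, train_vel[i], v)
            cur = clip_to_workspace((cur[0] + v[0] * dt, cur[1] + v[1] * dt))
            dec_pos[i] = cur
            dec_vel[i] = v
    return CalibrationTrial(
        target_index=target_index,
        block=block,
        rates=rates,
        train_pos=train_pos,
        train_vel=train_vel,
        decoded_pos=dec_pos,
        decoded_vel=dec_vel,
        target=target,
    )
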