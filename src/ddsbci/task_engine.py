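"""Workspace geometry and task state machines.

The workspace is a square of side 2 arbitrary units (a.u.) centered at the
origin; the cursor is a point (only its center counts for target hits) whose
position is the forward-Euler integral of the decoder's velocity command at
the 50 ms bin width, clipped to the workspace. A target "hit" requires the
cursor center to stay continuously inside the target for the full hold
period. Peripheral targets time out; the center target does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

WORKSPACE_SIDE = 2.0
BIN_DT = 0.05

#: Five phrases offered by the virtual keyboard typing task.
TYPING_PHRASES = (
    "Hello World",
    "Cyber Glove",
    "Potato Chips",
    "Neuroscience",
    "Game Over",
)


@dataclass(frozen=True)
class Workspace:
    """Closed square of side ``side_length`` centered at the origin."""

    side_length: float = WORKSPACE_SIDE

    @property
    def half(self) -> float:
        return self.side_length / 2.0


@dataclass(frozen=True)
class Target:
    """Circular target; hit tests use the cursor center only."""

    center: tuple[float, float]
    radius: float = 0.15
    label: str = ""

    def contains(self, pos) -> bool:
        dx = pos[0] - self.center[0]
        dy = pos[1] - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius


@dataclass
class TaskConfig:
    """Timing and geometry of one task variant.

    ``jabci_center_out``: 0.5 s hold, 20 s timeout, 8 directions x 8
    occurrences, targets of radius 0.15 a.u. at 0.85 a.u. from the origin.
    ``monkey_center_out``: 2.0 s timeout, 0.3 s hold, center hold drawn
    uniformly in [0.2, 0.5] s.
    """

    variant: str = "jabci_center_out"
    bin_dt: float = BIN_DT
    hold_time: float = 0.5
    timeout: float = 20.0
    n_directions: int = 8
    occurrences_per_target: int = 8
    target_radius: float = 0.15
    target_distance: float = 0.85
    center_hold_range: tuple[float, float] | None = None
    # Practical simulator bound: the center target has no timeout for the
    # subject, but a runaway decoder could otherwise stall the session; after
    # this many seconds the cursor is recentered automatically (logged).
    center_reacquire_limit: float = 30.0
    session_limit: float = 150.0 * 60.0

    @classmethod
    def jabci_center_out(cls, **kw) -> "TaskConfig":
        return cls(variant="jabci_center_out", **kw)

    @classmethod
    def monkey_center_out(cls, **kw) -> "TaskConfig":
        kw.setdefault("hold_time", 0.3)
        kw.setdefault("timeout", 2.0)
        kw.setdefault("center_hold_range", (0.2, 0.5))
        return cls(variant="monkey_center_out", **kw)

    @property
    def hold_bins(self) -> int:
        return int(math.ceil(self.hold_time / self.bin_dt - 1e-9))

    @property
    def timeout_bins(self) -> int:
        return int(math.ceil(self.timeout / self.bin_dt - 1e-9))

    def peripheral_targets(self) -> list[Target]:
        """Targets equally spaced on the circle, index 0 at East (+x)."""
        out = []
        for k in range(self.n_directions):
            ang = 2.0 * math.pi * k / self.n_directions
            out.append(
                Target(
                    center=(
                        self.target_distance * math.cos(ang),
                        self.target_distance * math.sin(ang),
                    ),
                    radius=self.target_radius,
                    label=str(k),
                )
            )
        return out

    def center_target(self) -> Target:
        # Center radius equals the peripheral radius (symmetric choice).
        return Target(center=(0.0, 0.0), radius=self.target_radius, label="center")


@dataclass
class CursorState:
    """Cursor kinematic state; the trailing constant-1 element used by the
    Kalman decoders lives in their state vector, not here."""

    px: float = 0.0
    py: float = 0.0
    vx: float = 0.0
    vy: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.px, self.py, self.vx, self.vy, 1.0])


def clip_to_workspace(pos, workspace: Workspace | None = None):
    """Clamp a position to the closed workspace square.

    Raises ``ValueError`` on non-finite input (a corrupted cursor state).
    """
    x, y = float(pos[0]), float(pos[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite cursor position {pos!r}")
    h = (workspace or Workspace()).half
    return (min(max(x, -h), h), min(max(y, -h), h))


def schedule_targets(n_directions: int, occurrences: int, seed) -> list[int]:
    """Block-randomized peripheral target order.

    Each consecutive block of ``n_directions`` entries is a fresh
    permutation of all directions, so every direction appears exactly
    ``occurrences`` times and the order is not predictable.
    """
    if n_directions < 1 or occurrences < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    order: list[int] = []
    for _ in range(occurrences):
        order.extend(rng.permutation(n_directions).tolist())
    return order


@dataclass
class TrialRecord:
    """Per-bin log of one trial (center reacquisition or peripheral reach)."""

    target: Target
    kind: str = "peripheral"  # or "center"
    trial_index: int = -1
    t_appear: float = 0.0
    hold_bins_required: int = 10
    timeout_bins: int | None = None  # None: no timeout (center target)
    # per-bin logs; row i is the state AFTER integrating command i
    t: list[float] = field(default_factory=list)
    pos: list[tuple[float, float]] = field(default_factory=list)
    cmd: list[tuple[float, float]] = field(default_factory=list)
    aux: list[dict] = field(default_factory=list)
    # running state
    hold_count: int = 0
    outcome: str | None = None  # "hit" | "timeout" | "error"
    t_hit: float | None = None
    forced_recenter: bool = False

    @property
    def active(self) -> bool:
        return self.outcome is None

    def positions(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)

    def commands(self) -> np.ndarray:
        return np.asarray(self.cmd, dtype=float)

    def times(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)


def step_trial(
    record: TrialRecord,
    command,
    config: TaskConfig,
    start_pos=None,
    aux: dict | None = None,
) -> TrialRecord:
    """Advance one 50 ms bin: Euler-integrate the command, clip, update the
    continuous-hold counter and the hit/timeout outcome.

    ``start_pos`` seeds the integration for the trial's first bin.
    """
    if not record.active:
        raise RuntimeError("trial already finished")
    vx, vy = float(command[0]), float(command[1])
    if not (math.isfinite(vx) and math.isfinite(vy)):
        record.outcome = "error"
        raise ValueError("non-finite velocity command")
    if record.pos:
        px, py = record.pos[-1]
    else:
        px, py = (0.0, 0.0) if start_pos is None else (start_pos[0], start_pos[1])
    new_pos = clip_to_workspace((px + vx * config.bin_dt, py + vy * config.bin_dt))
    record.pos.append(new_pos)
    record.cmd.append((vx, vy))
    record.t.append(record.t_appear + len(record.pos) * config.bin_dt)
    record.aux.append(aux or {})

    if record.target.contains(new_pos):
        record.hold_count += 1
        if record.hold_count >= record.hold_bins_required:
            record.outcome = "hit"
            record.t_hit = record.t[-1]
    else:
        record.hold_count = 0
        if record.timeout_bins is not None and len(record.pos) >= record.timeout_bins:
            record.outcome = "timeout"
    return record


def run_center_out_session(decoder, encoder, user, config: TaskConfig, seed) -> list[TrialRecord]:
    """Run a full closed-loop center-out session.

    Per-bin loop order: user intent -> encoder rates -> decoder command ->
    cursor integration. The session alternates a center target (no timeout;
    reacquisition is force-recentered after ``center_reacquire_limit`` so a
    runaway decoder cannot stall the run) with the block-randomized
    peripheral schedule. Returns all trial records, center segments included.
    """
    ss = np.random.SeedSequence(seed)
    sched_seed, noise_seed, user_seed, hold_seed = ss.spawn(4)
    order = schedule_targets(config.n_directions, config.occurrences_per_target, sched_seed)
    noise_rng = np.random.default_rng(noise_seed)
    user_rng = np.random.default_rng(user_seed)
    hold_rng = np.random.default_rng(hold_seed)
    if encoder.n_channels != decoder.n_channels:
        raise ValueError(
            f"encoder has {encoder.n_channels} channels, decoder expects {decoder.n_channels}"
        )

    peripherals = config.peripheral_targets()
    center = config.center_target()
    records: list[TrialRecord] = []
    pos = (0.0, 0.0)
    t_session = 0.0

    def run_one(target: Target, kind: str, idx: int, t0: float, start):
        nonlocal t_session
        if config.center_hold_range is not None and kind == "center":
            hold_s = hold_rng.uniform(*config.center_hold_range)
            hold_bins = int(math.ceil(hold_s / config.bin_dt - 1e-9))
        else:
            hold_bins = config.hold_bins
        rec = TrialRecord(
            target=target,
            kind=kind,
            trial_index=idx,
            t_appear=t0,
            hold_bins_required=hold_bins,
            timeout_bins=config.timeout_bins if kind == "peripheral" else None,
        )
        user.reset()
        decoder.reset(start)
        cur = start
        recenter_bins = int(round(config.center_reacquire_limit / config.bin_dt))
        while rec.active:
            intent = user.step(cur, target, user_rng)
            z = encoder.encode(intent, rng=noise_rng)
            cmd, aux = decoder.step(z, cur)
            step_trial(rec, cmd, config, start_pos=start, aux=aux)
            cur = rec.pos[-1]
            t_session += config.bin_dt
            if kind == "center" and len(rec.pos) >= recenter_bins:
                rec.outcome = "hit"
                rec.forced_recenter = True
                cur = (0.0, 0.0)
            if t_session >= config.session_limit:
                if rec.active:
                    rec.outcome = "timeout"
        return rec, cur

    for i, k in enumerate(order):
        rec_c, pos = run_one(center, "center", i, t_session, pos)
        records.append(rec_c)
        if t_session >= config.session_limit:
            break
        rec_p, pos = run_one(peripherals[k], "peripheral", i, t_session, pos)
        records.append(rec_p)
        if t_session >= config.session_limit:
            break
    return records


@dataclass(frozen=True)
class Key:
    legend: str
    center: tuple[float, float]
    side: float

    def contains(self, pos) -> bool:
        h = self.side / 2.0
        return (
            abs(pos[0] - self.center[0]) <= h
            and abs(pos[1] - self.center[1]) <= h
        )


@dataclass(frozen=True)
class KeyboardLayout:
    """3 x 10 square-key QWERTY grid filling the workspace width, with a gap
    between the outer key edges and the workspace boundary."""

    key_side: float
    gap: float
    keys: tuple[Key, ...]


_KEY_ROWS = (
    list("QWERTYUIOP"),
    list("ASDFGHJKL") + ["SPACE"],
    list("ZXCVBNM") + ["DEL", "DEL", "."],
)


def layout_keyboard(workspace: Workspace | None = None, gap: float = 0.01, keys_per_row: int = 10) -> KeyboardLayout:
    """Lay out the fixed 3-row, 10-column virtual keyboard.

    The horizontal geometry satisfies ``10 * key_side + 2 * gap = side``;
    with the 2 a.u. workspace and a 0.01 a.u. gap the key side is 0.198 a.u.
    """
    if keys_per_row != 10:
        raise ValueError("v1 supports the fixed 3x10 layout only")
    ws = workspace or Workspace()
    key_side = (ws.side_length - 2.0 * gap) / 10.0
    if key_side <= 0:
        raise ValueError("gap too large for workspace")
    keys = []
    x0 = -ws.half + gap + key_side / 2.0
    for r, legends in enumerate(_KEY_ROWS):
        y = (1 - r) * key_side  # rows stacked about the horizontal midline
        for c, legend in enumerate(legends):
            keys.append(Key(legend, (x0 + c * key_side, y), key_side))
    return KeyboardLayout(key_side=key_side, gap=gap, keys=tuple(keys))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def typing_score(typed: str, phrase: str, sign_convention: str = "as_printed") -> float:
    """Percent typing score from the Levenshtein distance LD to the phrase.

    ``as_printed`` follows S = 100 * (LD - c) / c where c = len(phrase);
    under it perfect typing scores -100 and typing nothing scores 0.
    ``corrected`` returns the accuracy-oriented S = 100 * (c - LD) / c.
    """
    if not phrase:
        raise ValueError("phrase must be non-empty")
    c = len(phrase)
    ld = levenshtein(typed, phrase)
    if sign_convention == "as_printed":
        return 100.0 * (ld - c) / c
    if sign_convention == "corrected":
        return 100.0 * (c - ld) / c
    raise ValueError(f"unknown sign convention {sign_convention!r}")
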