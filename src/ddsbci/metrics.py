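"""Per-trial kinematic metrics and offline/neural-population analyses.

Tortuosity follows the vasculature-literature definition: the pathlength-
normalized integral of |d kappa / dt| over an early trial window, where
kappa(t) is the instantaneous curvature (reciprocal circumradius of the
local circle). Straight segments and constant-curvature arcs both score
zero; only continually changing arcs are penalized.

The discrete Fréchet distance ("dog-leash" distance) is the minimum, over
monotone couplings of two point sequences, of the largest coupled point
distance — used both for offline decode-vs-training similarity and, on
PC-projected neural trajectories, for target separability via silhouette
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from ddsbci.task_engine import Target, TrialRecord, clip_to_workspace

TORTUOSITY_T1 = 0.25
TORTUOSITY_T2 = 3.0


def pathlength(trajectory) -> float:
    """Sum of segment lengths along the sampled trajectory (a.u.)."""
    pts = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _menger_curvature(a, b, c) -> float:
    """Curvature of the circumscribed circle through three points
    (4*area / product of side lengths); zero for collinear or degenerate
    triples."""
    ab = b - a
    bc = c - b
    ca = a - c
    cross = abs(ab[0] * bc[1] - ab[1] * bc[0])
    denom = np.linalg.norm(ab) * np.linalg.norm(bc) * np.linalg.norm(ca)
    if denom == 0.0:
        return 0.0
    return float(2.0 * cross / denom)


def curvature_series(points: np.ndarray) -> np.ndarray:
    """Discrete curvature at each interior sample from consecutive triples."""
    n = len(points)
    return np.array(
        [_menger_curvature(points[i - 1], points[i], points[i + 1]) for i in range(1, n - 1)]
    )


def tortuosity(times, positions, t1: float = TORTUOSITY_T1, t2: float = TORTUOSITY_T2) -> float:
    """T = (1/L) * integral_{t1}^{t2} |d kappa/dt| dt on the trial window.

    The window runs from ``t1`` to ``min(t2, trial end)`` (measured from
    the first sample); curvature comes from circumscribed circles of
    consecutive point triples, its time derivative from central finite
    differences, the integral from the trapezoid rule, and L is the
    pathlength of the windowed trajectory.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    rel = times - times[0]
    mask = (rel >= t1 - 1e-12) & (rel <= t2 + 1e-12)
    pts = positions[mask]
    tt = times[mask]
    if len(pts) < 4:
        raise ValueError("need at least 4 samples in the tortuosity window")
    L = pathlength(pts)
    if L == 0.0:
        warnings.warn("degenerate (stationary) trajectory; tortuosity set to 0")
        return 0.0
    kappa = curvature_series(pts)
    t_k = tt[1:-1]
    dk = np.gradient(kappa, t_k)
    integral = float(np.trapezoid(np.abs(dk), t_k))
    return integral / L


def dial_in_time(trial: TrialRecord, target: Target | None = None, hold: float | None = None,
                 bin_dt: float = 0.05) -> float:
    """Time spent within two target radii of the target center, with the
    final hold period subtracted on successful trials (floored at zero).

    Timeout trials report raw occupancy: there is no completed hold to
    subtract.
    """
    target = target or trial.target
    pos = trial.positions()
    if len(pos) == 0:
        return 0.0
    d = np.linalg.norm(pos - np.asarray(target.center), axis=1)
    occupancy = float(np.sum(d <= 2.0 * target.radius)) * bin_dt
    if trial.outcome == "hit":
        hold_s = hold if hold is not None else trial.hold_bins_required * bin_dt
        occupancy = max(0.0, occupancy - hold_s)
    return occupancy


def heading_fraction(trial: TrialRecord, target: Target | None = None,
                     home: Target | None = None) -> float:
    """Percent of counted bins whose command heads toward the target.

    A command counts as toward-target when its direction lies within the
    wedge subtended by the two rays from the cursor tangent to the target
    circle (half-angle asin(r/dist)); bins with the cursor inside the
    target always count as toward-target. Leading bins still inside the
    previous home target are discarded, as are zero-speed bins (their
    heading is undefined).
    """
    target = target or trial.target
    pos = trial.positions()
    cmd = trial.commands()
    if len(pos) == 0:
        return float("nan")
    # cursor position at which command i was issued (approximate the trial
    # start by undoing the first Euler step)
    at = np.vstack([pos[0] - cmd[0] * 0.05, pos[:-1]])
    counted = 0
    toward = 0
    in_home_prefix = True
    tc = np.asarray(target.center, dtype=float)
    for p, v in zip(at, cmd):
        if in_home_prefix and home is not None and home.contains(p):
            continue
        in_home_prefix = False
        if target.contains(p):
            counted += 1
            toward += 1
            continue
        speed = np.hypot(v[0], v[1])
        if speed == 0.0:
            continue
        d = tc - p
        dist = np.hypot(d[0], d[1])
        half_angle = np.arcsin(min(1.0, target.radius / dist))
        cosang = float(np.clip((v @ d) / (speed * dist), -1.0, 1.0))
        ang = np.arccos(cosang)
        counted += 1
        if ang <= half_angle + 1e-12:
            toward += 1
    if counted == 0:
        return float("nan")
    return 100.0 * toward / counted


@dataclass
class Histogram:
    counts: np.ndarray
    density: np.ndarray
    edges: np.ndarray
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def time_to_target_hist(trials, bin_width: float = 2.0, timeout: float = 20.0) -> Histogram:
    """Unit-area histogram of time-to-target over successful trials."""
    times = [
        t.t_hit - t.t_appear
        for t in trials
        if t.outcome == "hit" and t.kind == "peripheral"
    ]
    edges = np.arange(0.0, timeout + bin_width / 2, bin_width)
    counts, _ = np.histogram(times, bins=edges)
    n = int(counts.sum())
    density = counts / (n * bin_width) if n else counts.astype(float)
    return Histogram(counts=counts, density=density, edges=edges, n=n)


def speed_at_hit(trial: TrialRecord) -> float:
    """Command-speed magnitude at the single bin where the hold completed."""
    if trial.outcome != "hit":
        raise ValueError("speed_at_hit is defined only for successful trials")
    vx, vy = trial.cmd[-1]
    return float(np.hypot(vx, vy))


@dataclass
class MixingStats:
    """DDS selection-mixing occupancy: eta x eta grid of % time (diagonal =
    unmixed) and the per-bin largest normalized selection weight."""

    grid: np.ndarray  # (eta, eta) percent of counted bins
    largest_weights: np.ndarray  # per-bin
    n_bins: int

    @property
    def percent_unmixed(self) -> float:
        return float(np.trace(self.grid))


def mixing_stats(records, eta: int = 9) -> MixingStats:
    """Classify each DDS bin as unmixed or a mixed selection pair.

    Bins log the DDS weights w; after unit-sum normalization a bin is
    unmixed when one selection carries weight exactly 1, otherwise it is
    counted in the (unordered) cell of its two largest-weight selections
    (when more than two mix, the two largest are counted).
    """
    grid = np.zeros((eta, eta))
    largest = []
    n = 0
    for rec in records:
        for aux in rec.aux:
            if "w" not in aux:
                raise ValueError("mixing_stats requires a DDS session (logged weights)")
            w = np.asarray(aux["w"], dtype=float)
            tot = w.sum()
            if tot <= 0.0:
                wn = np.zeros(eta)
                wn[int(np.argmax(aux["p"]))] = 1.0
            else:
                wn = w / tot
            order = np.argsort(wn)[::-1]
            a, b = int(order[0]), int(order[1])
            largest.append(wn[a])
            n += 1
            if wn[a] >= 1.0 - 1e-12:
                grid[a, a] += 1
            else:
                i, j = min(a, b), max(a, b)
                grid[i, j] += 1
    if n == 0:
        raise ValueError("no bins to analyze")
    return MixingStats(grid=100.0 * grid / n, largest_weights=np.asarray(largest), n_bins=n)


def discrete_frechet(P, Q) -> float:
    """Discrete Fréchet distance between two point sequences (Euclidean
    ground distance, dynamic program over monotone couplings)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("sequences must be non-empty")
    d = cdist(P, Q)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def offline_similarity(dataset, runner, last_blocks: int = 5) -> np.ndarray:
    """Per-trial Fréchet distance between offline-decoded and training
    trajectories over the last calibration blocks (outliers excluded).

    The decoder is run open-loop on each trial's logged rates and its
    commands integrated from the workspace center.
    """
    trials = dataset.clean_trials()
    max_block = max(t.block for t in trials)
    use = [t for t in trials if t.block > max_block - last_blocks]
    dt = dataset.bin_dt
    out = []
    for t in use:
        runner.reset((0.0, 0.0))
        pos = (0.0, 0.0)
        decoded = []
        for z in t.rates:
            v, _ = runner.step(z, pos)
            pos = clip_to_workspace((pos[0] + v[0] * dt, pos[1] + v[1] * dt))
            decoded.append(pos)
        out.append(discrete_frechet(np.asarray(decoded), t.train_pos))
    return np.asarray(out)


@dataclass
class SeparabilityResult:
    projections: list  # per-trial (n_bins, 3) neural trajectories
    scores: np.ndarray  # silhouette per trial
    mean_score: float


def neural_separability(dataset, n_components: int = 3) -> SeparabilityResult:
    """Target separability of neural trajectories in PC space.

    All non-outlier calibration rates define the top principal components;
    each trial's rate time series is projected, pairwise discrete Fréchet
    distances between projected trajectories are computed, and each trial
    is silhouette-scored against its calibration-target cluster.
    """
    trials = dataset.clean_trials()
    labels = np.array([t.target_index for t in trials])
    if len(set(labels.tolist())) < 2 or min(np.bincount(labels)[np.bincount(labels) > 0]) < 2:
        raise ValueError("need >= 2 targets with >= 2 trials each")
    allrates = np.vstack([t.rates for t in trials])
    if np.linalg.matrix_rank(allrates - allrates.mean(axis=0)) < n_components:
        raise ValueError(f"rates span fewer than {n_components} dimensions")
    pca = PCA(n_components=n_components).fit(allrates)
    projections = [pca.transform(t.rates) for t in trials]
    n = len(projections)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = discrete_frechet(projections[i], projections[j])
    scores = silhouette_samples(D, labels, metric="precomputed")
    return SeparabilityResult(projections=projections, scores=scores,
                              mean_score=float(scores.mean()))
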