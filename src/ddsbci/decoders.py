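"""The five cursor-velocity decoders behind one interface.

Every decoder consumes one 50 ms bin of firing rates z (c channels) and
emits exactly one 2-D velocity command per bin; cursor position is always
the task engine's integral of those commands, never a decoder-internal
position estimate.

Continuous decoders
-------------------
* vKF — constant-gain velocity Kalman filter on the state
  x = [px, py, vx, vy, 1]:  x_t = A x_{t-1} + K (z_t - H A x_{t-1}).
  A, H come from least squares on calibration states; K is iterated to the
  steady-state Kalman gain on the calibration stream and then frozen.
* ReFIT — same update, but A encodes damped kinematics, H is fit on
  intention-relabeled states (velocity rotated toward the target, zeroed
  inside it), and position uncertainty is zeroed at every gain iteration
  because the displayed position is known exactly.
* DR-A — affine map x_t = B z_t fit on bins whose training-cursor speed is
  at least 0.03 a.u./s (assist blending happens at calibration time).
* WF — Wiener filter: the same affine map applied to the concatenation of
  the current bin and tau bins of rate history (tau = 8, i.e. 400 ms).

Discrete direction selection (DDS)
----------------------------------
A multinomial logistic model scores eta = 9 menu velocities (four cardinal
directions at fast 1.0 and slow 0.5 a.u./s, plus stop). Instead of winner
take all, selection probabilities are passed through the piecewise-linear
weighting  w_i = clip((p_i + gamma - 1) / (2 gamma - 1), 0, 1)  and the
command is the weight-averaged menu velocity. Probabilities below
1 - gamma contribute nothing; a probability above gamma fully determines
the command; gamma = 1 reduces to probability-weighted averaging.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

#: The eta = 9 selection menu, in (vx, vy) a.u./s:
#: fast/slow North, fast/slow East, fast/slow South, fast/slow West, stop.
MENU = np.array(
    [
        [0.0, 1.0],
        [0.0, 0.5],
        [1.0, 0.0],
        [0.5, 0.0],
        [0.0, -1.0],
        [0.0, -0.5],
        [-1.0, 0.0],
        [-0.5, 0.0],
        [0.0, 0.0],
    ]
)
STOP_INDEX = 8

DEFAULT_GAMMA = 0.85
DEFAULT_TAU = 8
DRA_SPEED_THRESHOLD = 0.03

STATE_DIM = 5  # [px, py, vx, vy, 1]


# --------------------------------------------------------------------------
# Kalman decoders


@dataclass
class KalmanModel:
    """Constant-gain Kalman filter matrices; K and P are frozen after fit."""

    A: np.ndarray  # (5, 5)
    H: np.ndarray  # (c, 5)
    K: np.ndarray  # (5, c)
    Q: np.ndarray  # (5, 5)
    R: np.ndarray  # (c, c)
    P: np.ndarray  # (5, 5)
    dt: float = 0.05
    frozen: bool = True
    kind: str = "vkf"

    @property
    def n_channels(self) -> int:
        return self.H.shape[0]


def _lstsq_coef(X: np.ndarray, Y: np.ndarray, name: str, check_rank: bool = True) -> np.ndarray:
    """Least-squares coefficient matrix C with Y ~ X @ C.T.

    ``check_rank=False`` permits the minimum-norm solution on wide designs
    (the Wiener filter's lagged design early in calibration)."""
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressors in {name}: rank {rank} < {X.shape[1]}"
            )
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef.T


def _residual_cov(X: np.ndarray, Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    resid = Y - X @ C.T
    return resid.T @ resid / max(1, resid.shape[0])


def _kalman_gain_recursion(
    A, H, Q, R, zero_position_uncertainty=False, tol=1e-12, max_iter=20000
):
    """Iterate the covariance/gain recursion to its fixed point.

    With ``zero_position_uncertainty`` the px/py rows and columns of the
    predicted error covariance are zeroed before each gain computation
    (ReFIT: the displayed position is known exactly).
    """
    c = H.shape[0]
    P = Q.copy()
    K = np.zeros((A.shape[0], c))
    eye = np.eye(A.shape[0])
    for _ in range(max_iter):
        P_minus = A @ P @ A.T + Q
        if zero_position_uncertainty:
            P_minus[:2, :] = 0.0
            P_minus[:, :2] = 0.0
        S = H @ P_minus @ H.T + R
        K_new = P_minus @ H.T @ np.linalg.pinv(S)
        P = (eye - K_new @ H) @ P_minus
        if zero_position_uncertainty:
            P[:2, :] = 0.0
            P[:, :2] = 0.0
        if np.max(np.abs(K_new - K)) < tol:
            K = K_new
            break
        K = K_new
    return K, P


def fit_vkf(dataset) -> KalmanModel:
    """Fit the velocity Kalman filter from a calibration dataset.

    A regresses x_t on x_{t-1} and H regresses z_t on x_t over all
    non-outlier calibration bins; Q and R are the residual covariances; the
    gain recursion is run to convergence and frozen.
    """
    X_prev, X_next = dataset.state_transition_pairs()
    X, Z = dataset.state_matrix(), dataset.rate_matrix()
    A = _lstsq_coef(X_prev, X_next, "state transition (A)")
    A[STATE_DIM - 1, :] = 0.0
    A[STATE_DIM - 1, STATE_DIM - 1] = 1.0  # the constant-1 element maps 1 -> 1
    H = _lstsq_coef(X, Z, "measurement model (H)")
    Q = _residual_cov(X_prev, X_next, A)
    Q[STATE_DIM - 1, :] = 0.0
    Q[:, STATE_DIM - 1] = 0.0
    R = _residual_cov(X, Z, H)
    K, P = _kalman_gain_recursion(A, H, Q, R)
    return KalmanModel(A=A, H=H, K=K, Q=Q, R=R, P=P, dt=dataset.bin_dt, kind="vkf")


def vkf_step(model: KalmanModel, x_prev: np.ndarray, z: np.ndarray) -> np.ndarray:
    """One constant-gain Kalman update: x_t = A x_{t-1} + K (z_t - H A x_{t-1})."""
    if not model.frozen:
        raise RuntimeError("Kalman gain must be frozen before closed-loop use")
    x_prev = np.asarray(x_prev, dtype=float)
    z = np.asarray(z, dtype=float)
    if x_prev.shape != (STATE_DIM,) or z.shape != (model.n_channels,):
        raise ValueError(
            f"dimension mismatch: state {x_prev.shape}, rates {z.shape}, "
            f"model expects ({STATE_DIM},) and ({model.n_channels},)"
        )
    x_pred = model.A @ x_prev
    return x_pred + model.K @ (z - model.H @ x_pred)


def fit_refit(dataset) -> KalmanModel:
    """Fit the ReFIT Kalman filter.

    Kinematic A (position integrates velocity at dt; per-axis velocity
    damping fit on intention-relabeled velocities), H fit on the relabeled
    states, and position uncertainty zeroed inside the gain recursion.
    """
    dt = dataset.bin_dt
    states = dataset.refit_states()  # intention-relabeled (n, 5) per trial
    X = np.vstack(states)
    prev = np.vstack([s[:-1] for s in states])
    nxt = np.vstack([s[1:] for s in states])

    A = np.zeros((STATE_DIM, STATE_DIM))
    A[0, 0] = A[1, 1] = 1.0
    A[0, 2] = A[1, 3] = dt
    for ax in range(2):
        v_prev, v_next = prev[:, 2 + ax], nxt[:, 2 + ax]
        denom = float(v_prev @ v_prev)
        A[2 + ax, 2 + ax] = float(v_prev @ v_next) / denom if denom > 0 else 0.0
    A[4, 4] = 1.0

    Z = dataset.rate_matrix()
    H = _lstsq_coef(X, Z, "measurement model (H)")
    Q = _residual_cov(prev, nxt, A)
    Q[:2, :] = 0.0
    Q[:, :2] = 0.0
    Q[4, :] = 0.0
    Q[:, 4] = 0.0
    R = _residual_cov(X, Z, H)
    K, P = _kalman_gain_recursion(A, H, Q, R, zero_position_uncertainty=True)
    return KalmanModel(A=A, H=H, K=K, Q=Q, R=R, P=P, dt=dt, kind="refit")


# --------------------------------------------------------------------------
# Direct-regression decoders


@dataclass
class LinearVelocityMap:
    """Affine rates-to-velocity map; tau > 0 adds rate history (Wiener filter)."""

    B: np.ndarray  # (2, c*(tau+1) + 1), offset last
    tau: int = 0
    n_channels: int = 0
    kind: str = "dra"


def fit_dra(dataset, speed_threshold: float = DRA_SPEED_THRESHOLD) -> LinearVelocityMap:
    """Fit the direct-regression decoder on bins moving at or above the
    speed threshold (training-cursor Euclidean speed, a.u./s)."""
    X, Z = dataset.state_matrix(), dataset.rate_matrix()
    speed = np.hypot(X[:, 2], X[:, 3])
    keep = speed >= speed_threshold
    if not np.any(keep):
        raise ValueError(
            f"no calibration bins at or above the {speed_threshold} a.u./s speed filter"
        )
    design = np.column_stack([Z[keep], np.ones(int(keep.sum()))])
    # minimum-norm solution: noiseless rates driven by 2-D velocity are
    # legitimately rank deficient
    B = _lstsq_coef(design, X[keep][:, 2:4], "direct regression (B)", check_rank=False)
    return LinearVelocityMap(B=B, tau=0, n_channels=Z.shape[1], kind="dra")


def dra_step(model: LinearVelocityMap, z: np.ndarray) -> np.ndarray:
    """x_t = B z_t with the trailing offset term."""
    z = np.asarray(z, dtype=float)
    if z.shape != (model.n_channels,):
        raise ValueError(f"expected {model.n_channels} rates, got {z.shape}")
    return model.B @ np.append(z, 1.0)


def fit_wf(dataset, tau: int = DEFAULT_TAU) -> LinearVelocityMap:
    """Fit the Wiener filter on tau+1 bins of rate history (zero-padded at
    each trial start; history never crosses trial boundaries)."""
    designs, targets = [], []
    for rates, states in dataset.trial_arrays():
        n, c = rates.shape
        lagged = [np.vstack([np.zeros((lag, c)), rates[: n - lag]]) for lag in range(tau + 1)]
        designs.append(np.column_stack(lagged + [np.ones(n)]))
        targets.append(states[:, 2:4])
    design = np.vstack(designs)
    Y = np.vstack(targets)
    B = _lstsq_coef(design, Y, "Wiener filter (B)", check_rank=False)
    return LinearVelocityMap(B=B, tau=tau, n_channels=design.shape[1] // (tau + 1), kind="wf")


def wf_step(model: LinearVelocityMap, history) -> np.ndarray:
    """x_t = B z_tau, z_tau = [z_t, z_{t-1}, ..., z_{t-tau}, 1].

    ``history`` is the last tau+1 frames ordered current-first.
    """
    frames = [np.asarray(f, dtype=float) for f in history]
    if len(frames) != model.tau + 1 or any(f.shape != (model.n_channels,) for f in frames):
        raise ValueError(
            f"need {model.tau + 1} frames of {model.n_channels} rates"
        )
    return model.B @ np.append(np.concatenate(frames), 1.0)


# --------------------------------------------------------------------------
# Discrete direction selection


@dataclass
class MultinomialSelectionModel:
    """DDS: multinomial logit coefficients over the selection menu."""

    B: np.ndarray  # (eta, c+1), offset last
    menu: np.ndarray = field(default_factory=lambda: MENU.copy())
    gamma: float = DEFAULT_GAMMA
    fallback: str = "argmax"  # all-weights-zero policy: "argmax" or "stop"
    kind: str = "dds"

    @property
    def n_channels(self) -> int:
        return self.B.shape[1] - 1

    @property
    def eta(self) -> int:
        return self.B.shape[0]


def fit_dds(
    dataset,
    gamma: float = DEFAULT_GAMMA,
    ridge: float = 1e-4,
    fallback: str = "argmax",
) -> MultinomialSelectionModel:
    """Fit the DDS multinomial logistic model on fifth-partition labels.

    Every menu selection must appear in the labels; a small ridge penalty
    keeps the fit well-posed on separable data.
    """
    Z = dataset.rate_matrix()
    labels = dataset.dds_labels()
    present = set(int(l) for l in labels)
    missing = sorted(set(range(len(MENU))) - present)
    if missing:
        raise ValueError(f"selections absent from calibration labels: {missing}")
    # ridge penalizes the mean log-likelihood: (1/n) sum loss + ridge/2 ||B||^2
    clf = LogisticRegression(
        C=1.0 / (ridge * Z.shape[0]), solver="lbfgs", max_iter=2000, tol=1e-6
    )
    clf.fit(Z, labels)
    # assemble the eta x (c+1) logit matrix in menu order
    eta, c = len(MENU), Z.shape[1]
    B = np.zeros((eta, c + 1))
    for row, cls in enumerate(clf.classes_):
        B[int(cls), :c] = clf.coef_[row]
        B[int(cls), c] = clf.intercept_[row]
    return MultinomialSelectionModel(B=B, gamma=gamma, fallback=fallback)


def softmax_probabilities(model: MultinomialSelectionModel, z: np.ndarray) -> np.ndarray:
    """Selection probabilities p_t = softmax(B [z; 1])."""
    z = np.asarray(z, dtype=float)
    if z.shape != (model.n_channels,):
        raise ValueError(f"expected {model.n_channels} rates, got {z.shape}")
    logits = model.B @ np.append(z, 1.0)
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def selection_weights(p: np.ndarray, gamma: float) -> np.ndarray:
    """Piecewise-linear mixing weights w_i = clip((p_i + g - 1)/(2g - 1), 0, 1).

    Probabilities below 1 - gamma get zero weight; above gamma, weight 1.
    """
    if not 0.5 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0.5, 1], got {gamma}")
    p = np.asarray(p, dtype=float)
    return np.clip((p + gamma - 1.0) / (2.0 * gamma - 1.0), 0.0, 1.0)


def mix_selections(w: np.ndarray, menu: np.ndarray = MENU, p: np.ndarray | None = None,
                   fallback: str = "argmax") -> np.ndarray:
    """Weight-averaged menu velocity, weights renormalized to unit sum.

    The L1 normalization is what makes gamma = 1 reduce exactly to the
    probability-weighted average. If every weight is zero (possible since a
    uniform 1/9 is below 1 - gamma), fall back to the argmax-probability
    selection (or stop, by configuration).
    """
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0.0:
        if fallback == "stop" or p is None:
            return np.zeros(2)
        return np.asarray(menu[int(np.argmax(p))], dtype=float)
    return (w / total) @ np.asarray(menu, dtype=float)


def dds_step(model: MultinomialSelectionModel, z: np.ndarray):
    """One DDS bin: softmax -> selection weights -> mixed menu velocity.

    Returns ``(velocity, aux)`` with the per-bin probabilities and weights
    logged in ``aux``.
    """
    p = softmax_probabilities(model, z)
    w = selection_weights(p, model.gamma)
    xi = mix_selections(w, model.menu, p=p, fallback=model.fallback)
    return xi, {"p": p, "w": w}


# --------------------------------------------------------------------------
# Closed-loop runners: uniform step interface for the task engine


class DecoderRunner:
    """Stateful per-session wrapper: reset per trial, one command per bin."""

    kind: str = ""

    @property
    def n_channels(self) -> int:  # pragma: no cover - overridden
        raise NotImplementedError

    def reset(self, pos) -> None:
        pass

    def step(self, z, pos):
        raise NotImplementedError


class KalmanRunner(DecoderRunner):
    """vKF / ReFIT: internal filter state, position synced to the display."""

    def __init__(self, model: KalmanModel):
        self.model = model
        self.kind = model.kind
        self._x = np.zeros(STATE_DIM)
        self._x[4] = 1.0

    @property
    def n_channels(self) -> int:
        return self.model.n_channels

    def reset(self, pos) -> None:
        self._x = np.array([pos[0], pos[1], 0.0, 0.0, 1.0])

    def step(self, z, pos):
        self._x[0], self._x[1] = pos[0], pos[1]
        self._x = vkf_step(self.model, self._x, np.asarray(z, dtype=float))
        return self._x[2:4].copy(), {}


class DRARunner(DecoderRunner):
    kind = "dra"

    def __init__(self, model: LinearVelocityMap):
        self.model = model

    @property
    def n_channels(self) -> int:
        return self.model.n_channels

    def step(self, z, pos):
        return dra_step(self.model, np.asarray(z, dtype=float)), {}


class WFRunner(DecoderRunner):
    kind = "wf"

    def __init__(self, model: LinearVelocityMap):
        self.model = model
        self._hist: deque = deque(maxlen=model.tau + 1)
        self.reset((0.0, 0.0))

    @property
    def n_channels(self) -> int:
        return self.model.n_channels

    def reset(self, pos) -> None:
        self._hist.clear()
        for _ in range(self.model.tau + 1):
            self._hist.appendleft(np.zeros(self.model.n_channels))

    def step(self, z, pos):
        self._hist.appendleft(np.asarray(z, dtype=float))
        return wf_step(self.model, list(self._hist)), {}


class DDSRunner(DecoderRunner):
    kind = "dds"

    def __init__(self, model: MultinomialSelectionModel):
        self.model = model

    @property
    def n_channels(self) -> int:
        return self.model.n_channels

    def step(self, z, pos):
        return dds_step(self.model, np.asarray(z, dtype=float))


_FITTERS = {
    "vkf": fit_vkf,
    "refit": fit_refit,
    "dra": fit_dra,
    "wf": fit_wf,
    "dds": fit_dds,
}

_RUNNERS = {
    "vkf": KalmanRunner,
    "refit": KalmanRunner,
    "dra": DRARunner,
    "wf": WFRunner,
    "dds": DDSRunner,
}

DECODER_KINDS = tuple(_FITTERS)


def fit_decoder(kind: str, dataset, **hyper):
    """Fit any decoder by name ('vkf', 'refit', 'dra', 'wf', 'dds')."""
    if kind not in _FITTERS:
        raise ValueError(f"unknown decoder {kind!r}; choose from {DECODER_KINDS}")
    return _FITTERS[kind](dataset, **hyper)


def make_decoder(kind: str, model) -> DecoderRunner:
    """Wrap a fitted model in its closed-loop runner."""
    if kind not in _RUNNERS:
        raise ValueError(f"unknown decoder {kind!r}; choose from {DECODER_KINDS}")
    return _RUNNERS[kind](model)
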