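"""Trajectory decoders: Kalman filter, recurrent (LSTM) and windowed linear
networks trained under MSE or the DILATE shape/time-distortion loss.

The recurrent decoder follows the standard LSTM gate equations (forget,
input, output gates and candidate cell state) with an exponential-linear
readout into 2-D velocity.  Training is per-trial (batch size 1) gradient
descent with adaptive moments; the DILATE loss backpropagates through the
soft-DTW machinery in :mod:`neuroscribe.alignment`, with model output and
label z-scored per dimension before the loss is evaluated.

Because decoding labels come from a guided-writing prompt, the subject's
actual movement timing may drift nonuniformly within a trial; MSE penalizes
any such misalignment pointwise, whereas DILATE scores the prediction
against the optimally warped label and separately penalizes the warp
itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import DilateParams, dilate_value_and_grad, normalized_dtw
from .kinematics import KinematicSeries, integrate_velocity

__all__ = [
    "LossSpec",
    "TrainConfig",
    "KalmanModel",
    "LSTMDecoder",
    "WindowedLinearDecoder",
    "fit_kalman",
    "kalman_decode",
    "train_decoder",
    "decode",
    "crossval_loco",
    "pearson_cc",
]


@dataclass(frozen=True)
class LossSpec:
    kind: str = "mse"  # "mse" | "dilate"
    dilate: DilateParams = field(default_factory=DilateParams)

    def __post_init__(self):
        if self.kind not in ("mse", "dilate"):
            raise ValueError(f"unknown loss kind {self.kind!r}")


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 0.001
    batch_size: int = 1
    dropout: float = 0.0
    seed: int = 0
    noise_scale: float = 0.0  # per-channel-SD multiple of augmentation noise
    patience: int = 10
    hidden_size: int = 512

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")


# ---------------------------------------------------------------------------
# Losses (value + gradient w.r.t. the prediction).
# ---------------------------------------------------------------------------


def _mse_value_and_grad(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    value = float(np.mean(diff**2))
    return value, 2.0 * diff / diff.size


def _zscore_with_grad(x: np.ndarray):
    """Per-dimension z-score and a closure backpropagating through it."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    safe = np.where(sd > 1e-12, sd, 1.0)
    u = (x - mu) / safe
    n = x.shape[0]

    def backward(g):
        # d/dx of (x - mu)/sd, accounting for mu(x) and sd(x).
        return (g - g.mean(axis=0) - u * np.mean(g * u, axis=0)) / safe

    return u, backward


def _dilate_value_and_grad(pred: np.ndarray, target: np.ndarray, params: DilateParams):
    zp, back = _zscore_with_grad(pred)
    zy = _zscore_with_grad(target)[0]
    value, gz = dilate_value_and_grad(zy, zp, params)
    return value, back(gz)


def loss_value_and_grad(pred: np.ndarray, target: np.ndarray, loss: LossSpec):
    if loss.kind == "mse":
        return _mse_value_and_grad(pred, target)
    return _dilate_value_and_grad(pred, target, loss.dilate)


# ---------------------------------------------------------------------------
# Adam over a dict of parameter arrays.
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Windowed linear decoder: one linear layer over a sliding feature window.
# ---------------------------------------------------------------------------


class WindowedLinearDecoder:
    """Linear readout of a +-``taps`` bin window of features into velocity.

    The window gives the otherwise instantaneous linear map the temporal
    context needed to express lead/lag and smoothing filters; taps=0 reduces
    to a plain per-bin linear layer.
    """

    def __init__(self, n_channels: int, taps: int = 8, n_out: int = 2, seed: int = 0):
        self.n_channels = n_channels
        self.taps = taps
        self.n_out = n_out
        width = n_channels * (2 * taps + 1)
        rng = np.random.default_rng(seed)
        self.params = {
            "W": rng.normal(0.0, 0.01, size=(n_out, width)),
            "b": np.zeros(n_out),
        }
        self._cache = None

    def _window(self, X: np.ndarray) -> np.ndarray:
        T, C = X.shape
        k = self.taps
        pad = np.zeros((k, C))
        Xp = np.vstack([pad, X, pad])
        cols = [Xp[i : i + T] for i in range(2 * k + 1)]
        return np.concatenate(cols, axis=1)

    def forward(self, X: np.ndarray) -> np.ndarray:
        Xw = self._window(np.asarray(X, float))
        self._cache = Xw
        return Xw @ self.params["W"].T + self.params["b"]

    def backward(self, dpred: np.ndarray) -> dict:
        Xw = self._cache
        return {"W": dpred.T @ Xw, "b": dpred.sum(axis=0)}


# ---------------------------------------------------------------------------
# LSTM decoder (numpy, manual BPTT).
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _delu(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0)))


class LSTMDecoder:
    """Single-layer LSTM with ELU + affine readout to 2-D velocity.

    Gate equations (i: input, f: forget, o: output, g: candidate cell):

        i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)      (likewise f, o)
        g_t = tanh   (W_c x_t + U_c h_{t-1} + b_c)
        c_t = f_t * c_{t-1} + i_t * g_t
        h_t = o_t * tanh(c_t)
        y_t = W_out elu(h_t) + b_out
    """

    def __init__(self, n_in: int, hidden: int = 512, n_out: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        s_in = 1.0 / np.sqrt(n_in)
        s_h = 1.0 / np.sqrt(hidden)
        self.n_in, self.hidden, self.n_out = n_in, hidden, n_out
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.params = {
            "W": rng.uniform(-s_in, s_in, size=(4 * hidden, n_in)),
            "U": rng.uniform(-s_h, s_h, size=(4 * hidden, hidden)),
            "b": b,
            "Wo": rng.uniform(-s_h, s_h, size=(n_out, hidden)),
            "bo": np.zeros(n_out),
        }
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        T = X.shape[0]
        H = self.hidden
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        pre = X @ W.T + b  # (T, 4H)
        i = np.empty((T, H)); f = np.empty((T, H))
        o = np.empty((T, H)); g = np.empty((T, H))
        c = np.empty((T, H)); h = np.empty((T, H))
        h_prev = np.zeros(H)
        c_prev = np.zeros(H)
        for t in range(T):
            z = pre[t] + U @ h_prev
            i[t] = _sigmoid(z[:H])
            f[t] = _sigmoid(z[H : 2 * H])
            o[t] = _sigmoid(z[2 * H : 3 * H])
            g[t] = np.tanh(z[3 * H :])
            c[t] = f[t] * c_prev + i[t] * g[t]
            h[t] = o[t] * np.tanh(c[t])
            h_prev, c_prev = h[t], c[t]
        eh = _elu(h)
        pred = eh @ self.params["Wo"].T + self.params["bo"]
        self._cache = (X, i, f, o, g, c, h, eh)
        return pred

    def backward(self, dpred: np.ndarray) -> dict:
        X, i, f, o, g, c, h, eh = self._cache
        T = X.shape[0]
        H = self.hidden
        U, Wo = self.params["U"], self.params["Wo"]
        grads = {
            "W": np.zeros_like(self.params["W"]),
            "U": np.zeros_like(U),
            "b": np.zeros_like(self.params["b"]),
            "Wo": dpred.T @ eh,
            "bo": dpred.sum(axis=0),
        }
        dh_readout = (dpred @ Wo) * _delu(h)
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            dh = dh_readout[t] + dh_next
            tc = np.tanh(c[t])
            dc = dh * o[t] * (1 - tc**2) + dc_next
            c_prev = c[t - 1] if t > 0 else np.zeros(H)
            h_prev = h[t - 1] if t > 0 else np.zeros(H)
            di = dc * g[t] * i[t] * (1 - i[t])
            df = dc * c_prev * f[t] * (1 - f[t])
            do = dh * tc * o[t] * (1 - o[t])
            dg = dc * i[t] * (1 - g[t] ** 2)
            dz = np.concatenate([di, df, do, dg])
            grads["W"] += np.outer(dz, X[t])
            grads["U"] += np.outer(dz, h_prev)
            grads["b"] += dz
            dh_next = U.T @ dz
            dc_next = dc * f[t]
        return grads


# ---------------------------------------------------------------------------
# Kalman filter (linear-Gaussian state space).
# ---------------------------------------------------------------------------


@dataclass
class KalmanModel:
    A: np.ndarray  # state transition (including constant bias channel)
    H: np.ndarray  # observation matrix
    Q: np.ndarray  # process noise covariance
    R: np.ndarray  # observation noise covariance
    x0: np.ndarray  # initial state mean
    P0: np.ndarray  # initial state covariance
    bias: bool = True  # state carries a trailing constant-1 channel


def _augment(states: np.ndarray, bias: bool) -> np.ndarray:
    if not bias:
        return states
    return np.hstack([states, np.ones((states.shape[0], 1))])


def fit_kalman(states: list, observations: list, bias: bool = True, ridge: float = 0.0) -> KalmanModel:
    """Least-squares fit of transition and observation models.

    ``states`` are trials of (T, 2) velocities; ``observations`` trials of
    (T, C) features.  A is fit from within-trial one-step pairs, H from all
    state/observation pairs; Q and R are residual covariances.  The control
    input B is fixed at zero.  Rank-deficient regressors fall back to a
    ridge solution with a warning.
    """
    xs = [_augment(np.asarray(s, float), bias) for s in states]
    zs = [np.asarray(z, float) for z in observations]
    prev = np.vstack([x[:-1] for x in xs])
    nxt = np.vstack([x[1:] for x in xs])
    allx = np.vstack(xs)
    allz = np.vstack(zs)

    def _lstsq(X, Y):
        if ridge > 0:
            G = X.T @ X + ridge * np.eye(X.shape[1])
            return np.linalg.solve(G, X.T @ Y)
        sol, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            warnings.warn("rank-deficient regressors; using ridge fallback")
            G = X.T @ X + 1e-8 * np.eye(X.shape[1])
            return np.linalg.solve(G, X.T @ Y)
        return sol

    A = _lstsq(prev, nxt).T
    H = _lstsq(allx, allz).T
    q_res = nxt - prev @ A.T
    r_res = allz - allx @ H.T
    Q = q_res.T @ q_res / max(1, q_res.shape[0] - 1)
    R = r_res.T @ r_res / max(1, r_res.shape[0] - 1)
    x0 = allx.mean(axis=0)
    P0 = np.cov(allx.T) + 1e-9 * np.eye(allx.shape[1])
    return KalmanModel(A=A, H=H, Q=Q, R=R, x0=x0, P0=P0, bias=bias)


def kalman_decode(model: KalmanModel, observations: np.ndarray, fs: float = 20.0) -> KinematicSeries:
    """Recursive predict/update decoding of one trial's feature sequence."""
    Z = np.asarray(observations, float)
    A, H, Q, R = model.A, model.H, model.Q, model.R
    x = model.x0.copy()
    P = model.P0.copy()
    n = A.shape[0]
    out = np.empty((Z.shape[0], n))
    I = np.eye(n)
    for k, z in enumerate(Z):
        x = A @ x  # predict (control input B u = 0)
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        try:
            K = np.linalg.solve(S.T, (P @ H.T).T).T
        except np.linalg.LinAlgError:
            warnings.warn("singular innovation covariance; using pseudo-inverse")
            K = P @ H.T @ np.linalg.pinv(S)
        x = x + K @ (z - H @ x)
        P = (I - K @ H) @ P
        out[k] = x
    vel = out[:, :2] if model.bias else out
    return KinematicSeries(velocity=vel, origin=np.zeros(vel.shape[1]), fs=fs)


# ---------------------------------------------------------------------------
# Gradient training loop (batch size 1).
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: object
    loss_history: np.ndarray  # per-epoch mean loss
    config: TrainConfig
    loss: LossSpec


def _as_target(t) -> np.ndarray:
    return t.velocity if isinstance(t, KinematicSeries) else np.asarray(t, float)


def train_decoder(
    features: list,
    targets: list,
    loss: LossSpec = LossSpec(),
    cfg: TrainConfig = TrainConfig(),
    model=None,
) -> TrainResult:
    """Train a sequence decoder on paired (features, kinematics) trials.

    ``features`` are trials of (T, channels); ``targets`` trials of (T, 2)
    velocity (or KinematicSeries).  Updates are per trial (batch size 1)
    with adaptive-moment gradient descent; training stops early when the
    smoothed loss has not improved for ``cfg.patience`` epochs.
    """
    feats = [np.asarray(f, float) for f in features]
    targs = [_as_target(t) for t in targets]
    if len(feats) != len(targs) or not feats:
        raise ValueError("need equally many non-empty feature and target trials")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = LSTMDecoder(feats[0].shape[1], hidden=cfg.hidden_size, seed=cfg.seed)
    opt = Adam(model.params, lr=cfg.lr)
    if cfg.noise_scale > 0:
        ch_sd = np.vstack(feats).std(axis=0)
    history = []
    best = np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(feats))
        epoch_losses = []
        for ti in order:
            X = feats[ti]
            if cfg.noise_scale > 0:
                X = X + rng.normal(0.0, cfg.noise_scale * ch_sd, size=X.shape)
            pred = model.forward(X)
            value, dpred = loss_value_and_grad(pred, targs[ti], loss)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite {loss.kind} loss at epoch {epoch}, trial {ti}"
                )
            grads = model.backward(dpred)
            opt.step(model.params, grads)
            epoch_losses.append(value)
        history.append(float(np.mean(epoch_losses)))
        smoothed = float(np.mean(history[-5:]))
        if smoothed < best - 1e-12:
            best = smoothed
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return TrainResult(model=model, loss_history=np.asarray(history), config=cfg, loss=loss)


def decode(model, features: np.ndarray, fs: float = 20.0, origin=None) -> KinematicSeries:
    """Run a trained decoder over one trial; position by velocity integration."""
    if isinstance(model, KalmanModel):
        return kalman_decode(model, features, fs=fs)
    vel = model.forward(np.asarray(features, float))
    org = np.zeros(vel.shape[1]) if origin is None else np.asarray(origin, float)
    return KinematicSeries(velocity=vel, origin=org, fs=fs)


# ---------------------------------------------------------------------------
# Leave-one-character-out cross-validation.
# ---------------------------------------------------------------------------


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-dimension Pearson correlation between two (T, d) series."""
    a = np.atleast_2d(np.asarray(a, float).T).T
    b = np.atleast_2d(np.asarray(b, float).T).T
    ccs = []
    for d in range(a.shape[1]):
        sa, sb = a[:, d].std(), b[:, d].std()
        if sa == 0 or sb == 0:
            ccs.append(0.0)
        else:
            ccs.append(float(np.corrcoef(a[:, d], b[:, d])[0, 1]))
    return float(np.mean(ccs))


@dataclass
class FoldResult:
    held_out: str
    train_size: int
    train_ids: list
    decoded: list  # (trial, KinematicSeries) pairs
    metrics: dict  # per-trial CC / MSE / normalized DTW


def crossval_loco(
    trials: list,
    loss: LossSpec = LossSpec(),
    cfg: TrainConfig = TrainConfig(),
    model_factory=None,
) -> list[FoldResult]:
    """Leave-one-character-out CV over a session's trials.

    Each fold holds out every repetition of one character; the master seed
    fans out one deterministic child seed per fold.  Characters without
    repetitions are skipped with a warning.  Trials expose ``char_id``,
    ``features`` (channels x bins) and ``label`` (KinematicSeries).
    """
    chars = sorted({t.char_id for t in trials})
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(chars))
    results = []
    for ci, char in enumerate(chars):
        train = [t for t in trials if t.char_id != char]
        test = [t for t in trials if t.char_id == char]
        if not test:
            warnings.warn(f"character {char!r} has no repetitions; skipped")
            continue
        fold_seed = int(seeds[ci].generate_state(1)[0] % (2**31))
        fold_cfg = replace(cfg, seed=fold_seed)
        feats = [t.features.T for t in train]
        targs = [t.label.velocity for t in train]
        if model_factory is None:
            model = LSTMDecoder(feats[0].shape[1], hidden=cfg.hidden_size, seed=fold_seed)
        else:
            model = model_factory(feats[0].shape[1], fold_seed)
        fit = train_decoder(feats, targs, loss=loss, cfg=fold_cfg, model=model)
        decoded = []
        metrics = {"cc": [], "mse": [], "ndtw": []}
        for t in test:
            series = decode(fit.model, t.features.T, fs=t.label.fs, origin=t.label.origin)
            decoded.append((t, series))
            metrics["cc"].append(pearson_cc(series.velocity, t.label.velocity))
            metrics["mse"].append(float(np.mean((series.velocity - t.label.velocity) ** 2)))
            metrics["ndtw"].append(normalized_dtw(t.label.velocity, series.velocity))
        results.append(
            FoldResult(
                held_out=char,
                train_size=len(train),
                train_ids=[(t.char_id, t.rep) for t in train],
                decoded=decoded,
                metrics=metrics,
            )
        )
    return results
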