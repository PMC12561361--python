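"""Simulation experiments: timeline misalignment, toy loss landscape,
multi-day fusion.

The misalignment experiment emulates a subject whose attempted-writing
timing drifts nonuniformly against the guiding prompt: each trial's
trajectory is re-timed by sorted uniform draws over the whole trial (the
spatial path is untouched), the re-timed velocity V' drives a fixed linear
encoder into simulated multichannel features, and decoders are trained
against the *prompted* velocity V under MSE or DILATE.  DILATE, scoring
shape after optimal warping, can exploit the misaligned training signal;
MSE averages over incompatible timings.

The toy landscape reduces this to one dimension: fit a scalar affine
readout a*x + b of a delayed copy x of a bump profile y, and map each loss
over an (a, b) grid.  MSE bottoms out at the flat line (a=0), DILATE at
the identity (a=1) — shape retained regardless of delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import recognition as rec
from .alignment import DilateParams, dilate_loss
from .decoders import (
    LossSpec,
    TrainConfig,
    WindowedLinearDecoder,
    decode,
    pearson_cc,
    train_decoder,
)
from .kinematics import differentiate_positions

__all__ = [
    "LinearEncoder",
    "LossLandscape",
    "resample_timeline",
    "linear_encode",
    "toy_landscape",
    "default_toy_inputs",
    "run_misalignment_experiment",
    "run_multiday_experiment",
    "multiday_fuse",
]


@dataclass
class LinearEncoder:
    """Fixed linear velocity-to-features map shared by all trials and days."""

    W: np.ndarray  # (channels, 2)
    b: np.ndarray  # (channels,)
    seed: int

    @classmethod
    def create(cls, n_channels: int = 96, seed: int = 12345) -> "LinearEncoder":
        rng = np.random.default_rng(seed)
        W = rng.normal(0.0, 1.0 / np.sqrt(2.0), size=(n_channels, 2))
        return cls(W=W, b=np.zeros(n_channels), seed=seed)

    def encode(self, velocity: np.ndarray, noise_sd: float = 0.0, rng=None) -> np.ndarray:
        out = np.asarray(velocity, float) @ self.W.T + self.b
        if noise_sd > 0:
            if rng is None:
                raise ValueError("noise requires an rng")
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        return out


def linear_encode(velocity: np.ndarray, encoder: LinearEncoder,
                  noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """S' = V' W^T + b (+ optional Gaussian noise)."""
    return encoder.encode(velocity, noise_sd=noise_sd, rng=rng)


def resample_timeline(positions: np.ndarray, rng, origin=None, fs: float = 20.0):
    """Re-time a trajectory by sorted uniform time draws (shape preserved).

    Draw as many time points as the trajectory has samples, uniformly over
    the whole index range, sort them, and read positions off the original
    space-time polyline by linear interpolation (velocity between samples is
    uniform).  Differentiating the re-timed positions gives the simulated
    "actual" velocity V'.  Returns (P', V').
    """
    P = np.asarray(positions, float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trajectory samples")
    u = np.sort(rng.uniform(0.0, n - 1.0, size=n))
    u = np.clip(u, 0.0, n - 1.0)
    grid = np.arange(n)
    P_res = np.column_stack([np.interp(u, grid, P[:, d]) for d in range(P.shape[1])])
    if origin is None:
        origin = P_res[0]
    V_res = differentiate_positions(P_res, origin, fs)
    return P_res, V_res


# ---------------------------------------------------------------------------
# Toy 1-D loss landscape.
# ---------------------------------------------------------------------------


@dataclass
class LossLandscape:
    a_grid: np.ndarray
    b_grid: np.ndarray
    surfaces: dict[str, np.ndarray]  # kind -> (len(a), len(b))
    argmin: dict[str, tuple[float, float]]


def default_toy_inputs():
    """Reference delayed-bump pair: y has a triangular bump (mean 1), x is
    the same profile delayed by 8 samples; grids cover a in [-2, 2] and b in
    [-1, 2] at step 0.1."""
    y = np.zeros(100)
    y[30:35] = [10.0, 25.0, 30.0, 25.0, 10.0]
    x = np.zeros(100)
    x[38:43] = [10.0, 25.0, 30.0, 25.0, 10.0]
    a_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10) + 0.0
    b_grid = np.round(np.arange(-1.0, 2.0 + 1e-9, 0.1), 10) + 0.0
    return y, x, a_grid, b_grid


def toy_landscape(
    y: np.ndarray,
    x: np.ndarray,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
    loss_kinds=("mse", "dilate"),
    dilate_params: DilateParams = DilateParams(alpha=0.5, gamma=0.001),
) -> LossLandscape:
    """Loss surfaces of the scalar readout a*x + b against the label y.

    No z-scoring is applied inside the losses (it would erase the (a, b)
    dependence).  The grid must contain the reference points a,b in {0, 1}
    and 0 so both canonical minima are representable.
    """
    a_grid = np.asarray(a_grid, float)
    b_grid = np.asarray(b_grid, float)
    for g, name in ((a_grid, "a_grid"), (b_grid, "b_grid")):
        if not (np.any(np.isclose(g, 0.0)) and np.any(np.isclose(g, 1.0))):
            raise ValueError(f"{name} must include 0 and 1")
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    surfaces = {k: np.empty((len(a_grid), len(b_grid))) for k in loss_kinds}
    for ia, a in enumerate(a_grid):
        for ib, b in enumerate(b_grid):
            pred = a * x + b
            for kind in loss_kinds:
                if kind == "mse":
                    val = float(np.mean((pred - y) ** 2))
                elif kind == "dilate":
                    val = dilate_loss(y, pred, dilate_params)
                else:
                    raise ValueError(f"unknown loss kind {kind!r}")
                surfaces[kind][ia, ib] = val
    argmin = {}
    for kind, S in surfaces.items():
        ia, ib = np.unravel_index(np.argmin(S), S.shape)
        argmin[kind] = (float(a_grid[ia]), float(b_grid[ib]))
    return LossLandscape(a_grid=a_grid, b_grid=b_grid, surfaces=surfaces, argmin=argmin)


# ---------------------------------------------------------------------------
# Misalignment decoding experiment.
# ---------------------------------------------------------------------------


def _char_folds(ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sorted(ids)))
    return [order[k::n_folds] for k in range(n_folds)]


def _zscore_fit(feats_train: list[np.ndarray]):
    stacked = np.vstack(feats_train)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _default_sim_cfg(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=100, lr=0.001, seed=seed, patience=15)


def _loss_spec(kind: str) -> LossSpec:
    return LossSpec(kind=kind) if kind in ("mse", "dilate") else LossSpec(kind)


def _train_eval_fold(
    train_trials,
    test_trials,
    loss_kind: str,
    cfg: TrainConfig,
    library: rec.TemplateLibrary,
    taps: int = 8,
):
    feats_tr = [t.features.T for t in train_trials]
    mu, sd = _zscore_fit(feats_tr)
    feats_tr = [(f - mu) / sd for f in feats_tr]
    targs_tr = [t.label.velocity for t in train_trials]
    model = WindowedLinearDecoder(feats_tr[0].shape[1], taps=taps, seed=cfg.seed)
    fit = train_decoder(feats_tr, targs_tr, loss=_loss_spec(loss_kind), cfg=cfg, model=model)
    rows = []
    for t in test_trials:
        pred = decode(fit.model, (t.features.T - mu) / sd, fs=t.label.fs).velocity
        res = rec.match(pred, library, metric="dtw", query_id=t.char_id)
        rows.append(
            {
                "char": t.char_id,
                "cc_vprime": pearson_cc(pred, t.true_velocity),
                "mse_vprime": float(np.mean((pred - t.true_velocity) ** 2)),
                "correct": bool(res.top1_correct),
                "pred": pred,
            }
        )
    return rows


def run_misalignment_experiment(
    corpus,
    loss_kinds=("mse", "dilate"),
    folds: int = 5,
    seed: int = 0,
    misalignment: bool = True,
    repetitions: int = 2,
    cfg: TrainConfig | None = None,
    noise_sd: float = 1.0,
    taps: int = 8,
) -> pd.DataFrame:
    """Character-level k-fold decoding of a simulated misaligned session.

    Returns one row per loss kind with the mean CC and MSE of the decoded
    velocity Vp against the re-timed ground truth V', and the DTW
    template-matching recognition rate of Vp against the prompted-velocity
    library.
    """
    from .synthetic import SessionSpec, simulate_session  # avoid import cycle

    spec = SessionSpec(
        repetitions=repetitions,
        misalignment=misalignment,
        noise_sd=noise_sd,
        seed=seed,
        drift=False,
    )
    session = simulate_session(corpus, spec)
    library = rec.build_library(corpus)
    fold_chars = _char_folds(corpus.ids, folds, seed)
    out = []
    for kind in loss_kinds:
        rows = []
        for k, chars in enumerate(fold_chars):
            chars = set(chars)
            train = [t for t in session.trials if t.char_id not in chars]
            test = [t for t in session.trials if t.char_id in chars]
            fold_cfg = cfg if cfg is not None else _default_sim_cfg(seed)
            fold_cfg = replace(fold_cfg, seed=fold_cfg.seed * 1000 + k)
            rows.extend(_train_eval_fold(train, test, kind, fold_cfg, library, taps=taps))
        df = pd.DataFrame(rows)
        out.append(
            {
                "loss": kind,
                "cc_vprime": df["cc_vprime"].mean(),
                "mse_vprime": df["mse_vprime"].mean(),
                "recognition_rate": df["correct"].mean(),
                "n_test": len(df),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Multi-day fusion experiment.
# ---------------------------------------------------------------------------


def multiday_fuse(day_datasets: list[list]) -> list:
    """Per-day, per-channel z-scoring followed by concatenation.

    ``day_datasets`` is a list (one entry per day) of trial lists; each
    trial's features are normalized with that day's own channel statistics,
    and the days are pooled into a single trial list.
    """
    pooled = []
    for day_trials in day_datasets:
        stacked = np.hstack([t.features for t in day_trials])
        mu = stacked.mean(axis=1, keepdims=True)
        sd = stacked.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        for t in day_trials:
            zt = replace(t, features=(t.features - mu) / sd)
            pooled.append(zt)
    return pooled


def run_multiday_experiment(
    corpus,
    n_days: int = 6,
    loss_kinds=("mse", "dilate"),
    seed: int = 0,
    repetitions: int = 1,
    cfg: TrainConfig | None = None,
    noise_sd: float = 1.0,
    test_every: int = 5,
    taps: int = 8,
) -> pd.DataFrame:
    """Decoding performance versus number of fused training days.

    Day 0 provides a fixed test set (every ``test_every``-th character);
    training pools the remaining characters from days 0..D-1 after per-day
    z-scoring.  Every day re-times each character's trajectory with fresh
    random draws through the same fixed encoder, with per-day gain/offset
    drift.  Reports the DTW recognition rate and the CC of the decoded
    velocity against each test trial's re-timed truth V'.
    """
    from .synthetic import SessionSpec, simulate_session  # avoid import cycle

    day_sessions = []
    for d in range(n_days):
        spec = SessionSpec(
            repetitions=repetitions,
            misalignment=True,
            noise_sd=noise_sd,
            seed=seed * 1009 + d,
            day=d,
            drift=True,
        )
        day_sessions.append(simulate_session(corpus, spec).trials)
    fused = multiday_fuse(day_sessions)
    library = rec.build_library(corpus)
    test_chars = set(sorted(corpus.ids)[::test_every])
    test = [t for t in fused if t.day == 0 and t.char_id in test_chars]
    rows = []
    for D in range(1, n_days + 1):
        train = [t for t in fused if t.day < D and t.char_id not in test_chars]
        for kind in loss_kinds:
            run_cfg = cfg if cfg is not None else _default_sim_cfg(seed)
            run_cfg = replace(run_cfg, seed=run_cfg.seed * 1000 + D)
            feats_tr = [t.features.T for t in train]
            targs_tr = [t.label.velocity for t in train]
            model = WindowedLinearDecoder(feats_tr[0].shape[1], taps=taps, seed=run_cfg.seed)
            fit = train_decoder(feats_tr, targs_tr, loss=_loss_spec(kind), cfg=run_cfg, model=model)
            ccs, hits = [], 0
            for t in test:
                pred = decode(fit.model, t.features.T, fs=t.label.fs).velocity
                ccs.append(pearson_cc(pred, t.true_velocity))
                hits += rec.match(pred, library, metric="dtw", query_id=t.char_id).top1_correct
            rows.append(
                {
                    "days": D,
                    "loss": kind,
                    "recognition_rate": hits / len(test),
                    "cc_vprime": float(np.mean(ccs)),
                    "n_train": len(train),
                    "n_test": len(test),
                }
            )
    return pd.DataFrame(rows)
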