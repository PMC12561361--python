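"""Sequence-alignment machinery: DTW, fastDTW, soft-DTW, and the DILATE loss.

Dynamic time warping (DTW) finds the minimum-cost monotone alignment between
two sequences, permitting local time stretch and compression.  Its smooth
relaxation (soft-DTW) replaces the hard minimum with a log-sum-exp
soft-minimum at temperature ``gamma``, which makes the alignment cost
differentiable and yields, through its gradient, a *relaxed optimal path*:
the Gibbs-expected alignment matrix with entries in [0, 1].

The DILATE loss combines two terms built on this machinery:

    DILATE_{alpha,gamma}(y, z) = alpha * softDTW_gamma(y, z)
                               + (1 - alpha) * softTDI_gamma(y, z)

where the soft temporal-distortion index (soft-TDI) is the inner product of
the relaxed path with a diagonal-deviation penalty Omega(i, j) = (i - j)^2,
optionally normalized by m*n.  The shape term rewards point-to-point
similarity after optimal warping; the time term penalizes warps that stray
from one-to-one timing.

All sequences are arrays of shape (length, dims); 1-D inputs are promoted.
Point costs are squared Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp

__all__ = [
    "DilateParams",
    "SoftAlignment",
    "OffsetStats",
    "pairwise_cost",
    "dtw",
    "fast_dtw",
    "soft_min",
    "soft_dtw",
    "relaxed_path",
    "soft_tdi",
    "dilate_loss",
    "dilate_value_and_grad",
    "warp_to_reference",
    "alignment_offsets",
    "normalized_dtw",
    "omega_matrix",
]


@dataclass(frozen=True)
class DilateParams:
    """Trade-off and smoothing parameters of the DILATE loss.

    alpha
        Weight of the shape (soft-DTW) term; 1 - alpha weighs the time
        (soft-TDI) term.  Must lie in [0, 1].
    gamma
        Soft-min temperature, > 0.  Smaller values approach hard DTW.
    omega_normalized
        If True (default) the diagonal-deviation penalty is
        (i - j)^2 / (m * n), which keeps the shape and time terms on
        comparable scales for alpha near 0.5.
    """

    alpha: float = 0.5
    gamma: float = 0.001
    omega_normalized: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass
class SoftAlignment:
    """Relaxed optimal path: Gibbs-expected cell occupancy, entries in [0,1]."""

    weights: np.ndarray
    gamma: float


@dataclass
class OffsetStats:
    """Per-point signed timing offsets (ms) read off a hard DTW path."""

    per_point_offsets: np.ndarray
    mean_ms: float
    mean_abs_ms: float
    sd_abs_ms: float


def _as_seq(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.ndim != 2 or y.shape[0] == 0:
        raise ValueError("sequence must be non-empty with shape (length, dims)")
    return y


def pairwise_cost(y, z) -> np.ndarray:
    """Squared-Euclidean point-to-point cost matrix Delta(y, z), shape (m, n)."""
    y, z = _as_seq(y), _as_seq(z)
    if y.shape[1] != z.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: {y.shape[1]} vs {z.shape[1]}"
        )
    diff = y[:, None, :] - z[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _backtrack(R: np.ndarray) -> list[tuple[int, int]]:
    # Tie-break: diagonal, then vertical (i-1, j), then horizontal (i, j-1).
    i, j = R.shape[0] - 1, R.shape[1] - 1
    path = [(i - 1, j - 1)]
    while i > 1 or j > 1:
        moves = (
            (R[i - 1, j - 1], i - 1, j - 1),
            (R[i - 1, j], i - 1, j),
            (R[i, j - 1], i, j - 1),
        )
        best = min(m[0] for m in moves)
        for cost, pi, pj in moves:
            if cost == best:
                i, j = pi, pj
                break
        path.append((i - 1, j - 1))
    path.reverse()
    return path


def dtw(y, z) -> tuple[float, list[tuple[int, int]]]:
    """Exact DTW distance and an optimal alignment path.

    Returns (distance, path) where the path is a list of 0-based (i, j)
    cells running from (0, 0) to (m-1, n-1) with steps in
    {(1,0), (0,1), (1,1)}.
    """
    D = pairwise_cost(y, z)
    R = _dp.dtw_table(D)
    return float(R[-1, -1]), _backtrack(R)


def normalized_dtw(y, z) -> float:
    """DTW distance divided by the warping-path length (number of cells)."""
    dist, path = dtw(y, z)
    return dist / len(path)


# ---------------------------------------------------------------------------
# fastDTW (Salvador & Chan): coarsen, solve recursively, refine in a window.
# ---------------------------------------------------------------------------


def _coarsen(y: np.ndarray) -> np.ndarray:
    n = y.shape[0] // 2 * 2
    half = (y[0:n:2] + y[1:n:2]) / 2.0
    if y.shape[0] % 2:
        half = np.vstack([half, y[-1:]])
    return half


def _expand_window(path, m, n, radius):
    """Project a coarse path onto the fine grid and dilate it by ``radius``."""
    mask = np.zeros((m, n), dtype=np.bool_)
    cells = set()
    for (ci, cj) in path:
        for di in (0, 1):
            for dj in (0, 1):
                cells.add((2 * ci + di, 2 * cj + dj))
    for (i, j) in cells:
        lo_i = max(0, i - radius)
        hi_i = min(m, i + radius + 1)
        lo_j = max(0, j - radius)
        hi_j = min(n, j + radius + 1)
        mask[lo_i:hi_i, lo_j:hi_j] = True
    # Guarantee an admissible corridor exists.
    mask[0, 0] = True
    mask[m - 1, n - 1] = True
    return mask


def _fast_dtw_rec(y, z, radius):
    m, n = y.shape[0], z.shape[0]
    if m <= radius + 2 or n <= radius + 2:
        return dtw(y, z)
    coarse_dist, coarse_path = _fast_dtw_rec(_coarsen(y), _coarsen(z), radius)
    mask = _expand_window(coarse_path, m, n, radius)
    D = pairwise_cost(y, z)
    R = _dp.dtw_windowed(D, mask)
    return float(R[-1, -1]), _backtrack(R)


def fast_dtw(y, z, radius: int = 1) -> tuple[float, list[tuple[int, int]]]:
    """Approximate DTW in O(n) via multiscale refinement.

    The search is restricted to a corridor of half-width ``radius`` around
    the path projected up from a coarsened copy of the inputs, so the
    returned distance is always >= the exact DTW distance, with equality on
    smooth sequences for radius >= 2.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    y, z = _as_seq(y), _as_seq(z)
    return _fast_dtw_rec(y, z, radius)


# ---------------------------------------------------------------------------
# Soft (differentiable) machinery.
# ---------------------------------------------------------------------------


def soft_min(values, gamma: float) -> float:
    """softmin_gamma(a_1..a_n) = -gamma * log sum_i exp(-a_i / gamma)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("soft_min of an empty list")
    m = a.min()
    return float(m - gamma * np.log(np.sum(np.exp(-(a - m) / gamma))))


def soft_dtw(y, z, gamma: float) -> float:
    """Soft-DTW value: soft-minimum of path costs over all admissible paths."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    D = pairwise_cost(y, z)
    R = _dp.softdtw_forward(D, float(gamma))
    return float(R[-1, -1])


def relaxed_path(y, z, gamma: float) -> SoftAlignment:
    """Relaxed optimal path A*_gamma = grad of softDTW w.r.t. the cost matrix."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    D = pairwise_cost(y, z)
    R = _dp.softdtw_forward(D, float(gamma))
    E = _dp.softdtw_backward(D, R, float(gamma))
    return SoftAlignment(weights=E, gamma=float(gamma))


def omega_matrix(m: int, n: int, normalized: bool = True) -> np.ndarray:
    """Diagonal-deviation penalty Omega(i, j) = (i - j)^2 [/ (m n)]."""
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]
    omega = (i - j).astype(float) ** 2
    if normalized:
        omega /= m * n
    return omega


def soft_tdi(y, z, params: DilateParams = DilateParams()) -> float:
    """Soft temporal-distortion index: <relaxed path, Omega>."""
    y, z = _as_seq(y), _as_seq(z)
    A = relaxed_path(y, z, params.gamma)
    omega = omega_matrix(y.shape[0], z.shape[0], params.omega_normalized)
    return float(np.sum(A.weights * omega))


def dilate_loss(y, z, params: DilateParams = DilateParams()) -> float:
    """DILATE_{alpha,gamma}(y, z) = alpha*softDTW + (1-alpha)*softTDI."""
    y, z = _as_seq(y), _as_seq(z)
    D = pairwise_cost(y, z)
    gamma = float(params.gamma)
    omega = omega_matrix(y.shape[0], z.shape[0], params.omega_normalized)
    if params.alpha == 1.0:
        R = _dp.softdtw_forward(D, gamma)
        return float(R[-1, -1])
    R = _dp.softdtw_forward(D, gamma)
    E = _dp.softdtw_backward(D, R, gamma)
    shape_term = float(R[-1, -1])
    time_term = float(np.sum(E * omega))
    return params.alpha * shape_term + (1.0 - params.alpha) * time_term


def dilate_value_and_grad(
    target, pred, params: DilateParams = DilateParams()
) -> tuple[float, np.ndarray]:
    """DILATE value and its gradient with respect to ``pred``.

    ``target`` plays the role of y (length m), ``pred`` of z (length n).
    The shape-term gradient is the relaxed path E; the time-term gradient is
    the exact Hessian-vector product of soft-DTW with Omega, obtained by
    forward-mode differentiation of both DP recursions.  Both are chained
    through dDelta/dpred, with Omega held constant.
    """
    y, z = _as_seq(target), _as_seq(pred)
    D = pairwise_cost(y, z)
    gamma = float(params.gamma)
    alpha = float(params.alpha)
    omega = omega_matrix(y.shape[0], z.shape[0], params.omega_normalized)
    if alpha == 1.0:
        R = _dp.softdtw_forward(D, gamma)
        E = _dp.softdtw_backward(D, R, gamma)
        value = float(R[-1, -1])
        G = E
    else:
        R, Rd = _dp.softdtw_forward_jvp(D, omega, gamma)
        E, Ed = _dp.softdtw_backward_jvp(D, omega, R, Rd, gamma)
        shape_term = float(R[-1, -1])
        time_term = float(np.sum(E * omega))
        value = alpha * shape_term + (1.0 - alpha) * time_term
        G = alpha * E + (1.0 - alpha) * Ed
    # dDelta[i, j] / dz[j] = 2 (z_j - y_i)
    grad = 2.0 * (G.sum(axis=0)[:, None] * z - G.T @ y)
    return value, grad


# ---------------------------------------------------------------------------
# Hard-path utilities: warping alignment and timing-offset statistics.
# ---------------------------------------------------------------------------


def warp_index(reference, predicted) -> np.ndarray:
    """index_i = min{ j | A[i, j] = 1 } along the optimal hard path."""
    _, path = dtw(reference, predicted)
    m = _as_seq(reference).shape[0]
    index = np.full(m, -1, dtype=int)
    for (i, j) in path:
        if index[i] < 0:
            index[i] = j
    return index


def warp_to_reference(reference, predicted) -> np.ndarray:
    """Align ``predicted`` onto the timeline of ``reference``.

    Output element i is predicted[index_i] with index_i the smallest
    predicted-index aligned to reference point i by the optimal DTW path, so
    the output always has the reference's length.
    """
    z = _as_seq(predicted)
    index = warp_index(reference, predicted)
    return z[index]


def alignment_offsets(label, decoded, bin_ms: float = 50.0) -> OffsetStats:
    """Signed per-point timing offsets (i - index_i) * bin_ms along the path.

    Offsets are integer multiples of the kinematic bin.  The mean is reported
    both signed and absolute; the SD is taken over absolute offsets within
    the trial.
    """
    index = warp_index(label, decoded)
    offsets = (np.arange(len(index)) - index) * float(bin_ms)
    abs_off = np.abs(offsets)
    return OffsetStats(
        per_point_offsets=offsets,
        mean_ms=float(offsets.mean()),
        mean_abs_ms=float(abs_off.mean()),
        sd_abs_ms=float(abs_off.std()),
    )
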