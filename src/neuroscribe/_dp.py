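"""Numba-jitted dynamic-programming kernels for (soft-)DTW.

These kernels operate on a precomputed cost matrix ``D`` (m x n, squared
Euclidean point costs).  Everything is float64; the smoothed recursions use
max-shifted log-sum-exp so they stay finite for gamma as small as 1e-4 on
costs of order 1e3.

The forward-mode (JVP) kernels differentiate both the forward soft-DTW
recursion and its backward (gradient) recursion along a direction matrix
``V``; this yields the exact Hessian-vector product ``H(softDTW) @ V`` needed
for the gradient of the soft temporal-distortion term, where V is the
diagonal-deviation penalty.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _softmin3(a, b, c, gamma):
    m = min(a, min(b, c))
    if m == np.inf:
        return np.inf
    s = (
        np.exp(-(a - m) / gamma)
        + np.exp(-(b - m) / gamma)
        + np.exp(-(c - m) / gamma)
    )
    return -gamma * np.log(s) + m


@njit(cache=True)
def softdtw_forward(D, gamma):
    """Cumulative soft cost table R, shape (m+1, n+1); value at R[m, n]."""
    m, n = D.shape
    R = np.full((m + 1, n + 1), np.inf)
    R[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            R[i, j] = D[i - 1, j - 1] + _softmin3(
                R[i - 1, j], R[i - 1, j - 1], R[i, j - 1], gamma
            )
    return R


@njit(cache=True)
def softdtw_backward(D, R, gamma):
    """Gradient of softDTW w.r.t. D: the relaxed alignment matrix E (m x n)."""
    m, n = D.shape
    E = np.zeros((m + 2, n + 2))
    E[m + 1, n + 1] = 1.0
    Rb = np.full((m + 2, n + 2), -np.inf)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Rb[i, j] = R[i, j]
    Rb[m + 1, n + 1] = R[m, n]
    Db = np.zeros((m + 2, n + 2))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Db[i, j] = D[i - 1, j - 1]
    for i in range(m, 0, -1):
        for j in range(n, 0, -1):
            a = 0.0
            b = 0.0
            c = 0.0
            if Rb[i + 1, j] > NEG_INF:
                a = np.exp((Rb[i + 1, j] - Rb[i, j] - Db[i + 1, j]) / gamma)
            if Rb[i, j + 1] > NEG_INF:
                b = np.exp((Rb[i, j + 1] - Rb[i, j] - Db[i, j + 1]) / gamma)
            if Rb[i + 1, j + 1] > NEG_INF:
                c = np.exp((Rb[i + 1, j + 1] - Rb[i, j] - Db[i + 1, j + 1]) / gamma)
            E[i, j] = a * E[i + 1, j] + b * E[i, j + 1] + c * E[i + 1, j + 1]
    return E[1 : m + 1, 1 : n + 1]


@njit(cache=True)
def softdtw_forward_jvp(D, V, gamma):
    """Forward table R and its directional derivative Rdot along V."""
    m, n = D.shape
    R = np.full((m + 1, n + 1), np.inf)
    Rd = np.zeros((m + 1, n + 1))
    R[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            r1 = R[i - 1, j]
            r2 = R[i - 1, j - 1]
            r3 = R[i, j - 1]
            s = _softmin3(r1, r2, r3, gamma)
            R[i, j] = D[i - 1, j - 1] + s
            w1 = 0.0
            w2 = 0.0
            w3 = 0.0
            if r1 < np.inf:
                w1 = np.exp((s - r1) / gamma)
            if r2 < np.inf:
                w2 = np.exp((s - r2) / gamma)
            if r3 < np.inf:
                w3 = np.exp((s - r3) / gamma)
            Rd[i, j] = (
                V[i - 1, j - 1]
                + w1 * Rd[i - 1, j]
                + w2 * Rd[i - 1, j - 1]
                + w3 * Rd[i, j - 1]
            )
    return R, Rd


@njit(cache=True)
def softdtw_backward_jvp(D, V, R, Rd, gamma):
    """E and its directional derivative Edot along V (exact HVP rows)."""
    m, n = D.shape
    E = np.zeros((m + 2, n + 2))
    Ed = np.zeros((m + 2, n + 2))
    E[m + 1, n + 1] = 1.0
    Rb = np.full((m + 2, n + 2), -np.inf)
    Rbd = np.zeros((m + 2, n + 2))
    Db = np.zeros((m + 2, n + 2))
    Vb = np.zeros((m + 2, n + 2))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Rb[i, j] = R[i, j]
            Rbd[i, j] = Rd[i, j]
            Db[i, j] = D[i - 1, j - 1]
            Vb[i, j] = V[i - 1, j - 1]
    Rb[m + 1, n + 1] = R[m, n]
    Rbd[m + 1, n + 1] = Rd[m, n]
    for i in range(m, 0, -1):
        for j in range(n, 0, -1):
            ea = 0.0
            eb = 0.0
            ec = 0.0
            da = 0.0
            db = 0.0
            dc = 0.0
            if Rb[i + 1, j] > NEG_INF:
                ea = np.exp((Rb[i + 1, j] - Rb[i, j] - Db[i + 1, j]) / gamma)
                da = ea * (Rbd[i + 1, j] - Rbd[i, j] - Vb[i + 1, j]) / gamma
            if Rb[i, j + 1] > NEG_INF:
                eb = np.exp((Rb[i, j + 1] - Rb[i, j] - Db[i, j + 1]) / gamma)
                db = eb * (Rbd[i, j + 1] - Rbd[i, j] - Vb[i, j + 1]) / gamma
            if Rb[i + 1, j + 1] > NEG_INF:
                ec = np.exp((Rb[i + 1, j + 1] - Rb[i, j] - Db[i + 1, j + 1]) / gamma)
                dc = ec * (Rbd[i + 1, j + 1] - Rbd[i, j] - Vb[i + 1, j + 1]) / gamma
            E[i, j] = ea * E[i + 1, j] + eb * E[i, j + 1] + ec * E[i + 1, j + 1]
            Ed[i, j] = (
                da * E[i + 1, j]
                + ea * Ed[i + 1, j]
                + db * E[i, j + 1]
                + eb * Ed[i, j + 1]
                + dc * E[i + 1, j + 1]
                + ec * Ed[i + 1, j + 1]
            )
    return E[1 : m + 1, 1 : n + 1], Ed[1 : m + 1, 1 : n + 1]


@njit(cache=True)
def dtw_table(D):
    """Hard-min cumulative cost table (m+1, n+1)."""
    m, n = D.shape
    R = np.full((m + 1, n + 1), np.inf)
    R[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = R[i - 1, j - 1]
            if R[i - 1, j] < best:
                best = R[i - 1, j]
            if R[i, j - 1] < best:
                best = R[i, j - 1]
            R[i, j] = D[i - 1, j - 1] + best
    return R


@njit(cache=True)
def dtw_windowed(D, mask):
    """Hard DTW restricted to mask[i, j] == True cells (fastDTW inner step)."""
    m, n = D.shape
    R = np.full((m + 1, n + 1), np.inf)
    R[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if not mask[i - 1, j - 1]:
                continue
            best = R[i - 1, j - 1]
            if R[i - 1, j] < best:
                best = R[i - 1, j]
            if R[i, j - 1] < best:
                best = R[i, j - 1]
            R[i, j] = D[i - 1, j - 1] + best
    return R
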