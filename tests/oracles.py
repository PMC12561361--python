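"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programming: paths are
enumerated exhaustively and quantities computed from their definitions, so
they stay independent of the code paths they check (practical only for
sequence lengths <= ~6).
"""

import numpy as np


def enumerate_paths(m: int, n: int):
    """All admissible monotone alignment paths from (0,0) to (m-1,n-1)."""

    def rec(i, j):
        if i == m - 1 and j == n - 1:
            yield [(i, j)]
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < n:
                for rest in rec(ni, nj):
                    yield [(i, j)] + rest

    return list(rec(0, 0))


def path_costs(D: np.ndarray):
    paths = enumerate_paths(*D.shape)
    costs = np.array([sum(D[i, j] for i, j in p) for p in paths])
    return paths, costs


def dtw_brute(D: np.ndarray) -> float:
    return float(path_costs(D)[1].min())


def softdtw_brute(D: np.ndarray, gamma: float) -> float:
    _, costs = path_costs(D)
    m = costs.min()
    return float(m - gamma * np.log(np.sum(np.exp(-(costs - m) / gamma))))


def gibbs_path_average(D: np.ndarray, gamma: float) -> np.ndarray:
    """Expected path-indicator matrix under the Gibbs measure over paths."""
    paths, costs = path_costs(D)
    w = np.exp(-(costs - costs.min()) / gamma)
    w /= w.sum()
    A = np.zeros(D.shape)
    for pw, path in zip(w, paths):
        for i, j in path:
            A[i, j] += pw
    return A


def soft_tdi_brute(D: np.ndarray, gamma: float, omega: np.ndarray) -> float:
    paths, costs = path_costs(D)
    w = np.exp(-(costs - costs.min()) / gamma)
    w /= w.sum()
    tdis = np.array([sum(omega[i, j] for i, j in p) for p in paths])
    return float(np.sum(w * tdis))
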