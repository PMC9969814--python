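"""Independent brute-force DTW oracle: explicit monotone-path enumeration.

Deliberately avoids the dynamic-programming recurrence used by the
implementation — every boundary-to-boundary monotone warping path through
the alignment grid is enumerated once per grid shape, and the alignment
cost is the minimum of the summed |x_i - y_j| local costs over those
paths.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def monotone_paths(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Every monotone path from (0,0) to (n-1,m-1) with steps (1,0),(0,1),(1,1)."""
    if n < 1 or m < 1:
        raise ValueError("grid dimensions must be positive")
    if n == 1 and m == 1:
        return (((0, 0),),)
    out = []
    if n > 1 and m > 1:
        out += [p + ((n - 1, m - 1),) for p in monotone_paths(n - 1, m - 1)]
    if n > 1:
        out += [p + ((n - 1, m - 1),) for p in monotone_paths(n - 1, m)]
    if m > 1:
        out += [p + ((n - 1, m - 1),) for p in monotone_paths(n, m - 1)]
    return tuple(out)


def dtw_bruteforce(x, y) -> float:
    """Minimum path cost by direct enumeration (small inputs only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = np.inf
    for path in monotone_paths(len(x), len(y)):
        cost = sum(abs(x[i] - y[j]) for i, j in path)
        best = min(best, cost)
    return float(best)


def _paths_flat(n: int, m: int) -> np.ndarray:
    """Paths as flat cell indices, padded with the index of a sentinel
    zero-cost cell appended at position n*m."""
    paths = monotone_paths(n, m)
    length = max(len(p) for p in paths)
    arr = np.full((len(paths), length), n * m, dtype=np.int64)
    for k, p in enumerate(paths):
        arr[k, : len(p)] = [i * m + j for i, j in p]
    return arr


def dtw_bruteforce_many(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs brute-force DTW between rows of X (Na,n) and Y (Nb,m).

    Same enumeration as :func:`dtw_bruteforce`, vectorized: per left-hand
    sequence, local-cost grids against every right-hand sequence are
    gathered along each enumerated path and the per-pair minimum taken.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = X.shape[1], Y.shape[1]
    P = _paths_flat(n, m)
    out = np.empty((len(X), len(Y)))
    for a, x in enumerate(X):
        grid = np.abs(x[:, None] - Y[:, None, :]).reshape(len(Y), n * m)
        grid = np.concatenate([grid, np.zeros((len(Y), 1))], axis=1)
        acc = np.zeros((len(Y), P.shape[0]))
        for k in range(P.shape[1]):
            acc += grid[:, P[:, k]]
        out[a] = acc.min(axis=1)
    return out
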