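"""Shape-based K=2 clustering of SCG beats: DTW dissimilarity + k-medoids.

Respiration stretches and reshapes SCG beats, so Euclidean distance between
beats of unequal length is ill-defined and misaligned. Dynamic time warping
(DTW) scores the optimal monotone alignment instead; k-medoids with DTW then
splits the beats into two respiration-linked morphology groups, each
represented by its medoid (the member minimizing summed DTW to the rest).

DTW here uses local cost |x_i - y_j| and the symmetric unit-weight step set
{diagonal, up, right} with a boundary-to-boundary path — the plain
O(l^2) recurrence, with the inner loop JIT-compiled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .segment import BeatSet

logger = logging.getLogger("scgvar")

#: respiratory phases counted as the inspiration regime (planted cluster 1)
REGIME1_PHASES = frozenset({"LLV-INS", "HLV-INS"})


@njit(cache=True)
def _dtw_core(x: np.ndarray, y: np.ndarray, window: int) -> float:
    n, m = len(x), len(y)
    inf = np.inf
    prev = np.full(m + 1, inf)
    cur = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = inf
        j_lo, j_hi = 1, m
        if window >= 0:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        for j in range(j_lo, j_hi + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(x: np.ndarray, y: np.ndarray, window: int | None = None) -> float:
    """DTW alignment cost between two sequences (lengths may differ).

    ``window`` optionally applies a Sakoe-Chiba band of that half-width
    around the diagonal; by default the warp is unconstrained.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW is undefined for empty sequences")
    w = -1 if window is None else int(window)
    if w >= 0:
        w = max(w, abs(len(x) - len(y)))  # band must reach the corner
    return float(_dtw_core(x, y, w))


def dtw_distance_matrix(
    waveforms: list[np.ndarray], window: int | None = None
) -> np.ndarray:
    """Symmetric pairwise DTW matrix over a list of beats."""
    n = len(waveforms)
    seqs = [np.ascontiguousarray(w, dtype=np.float64) for w in waveforms]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(seqs[i], seqs[j], window)
    return D


# ------------------------------------------------------------- k-medoids

@dataclass
class ClusterResult:
    """Converged K=2 assignment with medoids and iteration trace."""

    labels: np.ndarray           # {1, 2} per beat
    medoid_index_1: int
    medoid_index_2: int
    C1: np.ndarray               # medoid waveforms (normalized scale)
    C2: np.ndarray
    n1: int
    n2: int
    iterations: int
    converged: bool
    seed: int
    objective_trace: list[float]

    def __post_init__(self) -> None:
        if self.n1 + self.n2 != len(self.labels):
            raise ValueError("cluster sizes must sum to the beat count")
        if self.labels[self.medoid_index_1] != 1 or self.labels[self.medoid_index_2] != 2:
            raise ValueError("each medoid must carry its own cluster's label")

    @property
    def medoid_indices(self) -> tuple[int, int]:
        return self.medoid_index_1, self.medoid_index_2

    def to_json_dict(self) -> dict:
        return {
            "labels": [int(v) for v in self.labels],
            "medoid_index_1": int(self.medoid_index_1),
            "medoid_index_2": int(self.medoid_index_2),
            "n1": int(self.n1),
            "n2": int(self.n2),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "objective_trace": [float(v) for v in self.objective_trace],
        }


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # ties go to the lower cluster index (np.argmin convention)
    return np.argmin(D[medoids, :], axis=0)


def _update_medoid(D: np.ndarray, members: np.ndarray) -> int:
    sub = D[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def k_medoids_dtw(
    bs: BeatSet,
    K: int = 2,
    max_iter: int = 100,
    seed: int = 0,
    init: str = "random",
    window: int | None = None,
    D: np.ndarray | None = None,
) -> ClusterResult:
    """K-medoids over DTW distances between (normalized) beats.

    Alternates nearest-medoid assignment with the medoid update
    C_j = argmin_{y in cluster j} sum_i dtw(y, X_ij) until no label
    changes or ``max_iter`` sweeps. An emptied cluster is re-seeded with
    the beat farthest from the other medoid. After convergence clusters
    are relabeled so that cluster 1 has the higher mean heart rate, making
    labels comparable across runs and recordings.

    ``init='random'`` draws K distinct beats with the given seed;
    ``init='farthest'`` deterministically takes the farthest pair (K=2).
    A precomputed distance matrix may be passed via ``D``.
    """
    n = len(bs)
    if K != 2:
        raise ValueError("this pipeline clusters into exactly two groups")
    if n < K:
        raise ValueError(f"need at least {K} beats, got {n}")
    if not all(b.normalized for b in bs.beats):
        raise ValueError("beats must be normalized before clustering")

    waveforms = bs.waveforms()
    if D is None:
        D = dtw_distance_matrix(waveforms, window)

    if init == "random":
        rng = np.random.default_rng(seed)
        medoids = rng.choice(n, size=K, replace=False)
    elif init == "farthest":
        medoids = np.array(np.unravel_index(np.argmax(D), D.shape))
    else:
        raise ValueError(f"unknown init {init!r}")

    labels = _assign(D, medoids)
    for j in range(K):
        labels[medoids[j]] = j
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(K):
            members = np.flatnonzero(labels == j)
            if len(members) == 0:
                other = int(medoids[1 - j])
                cand = int(np.argmax(D[other]))
                if cand == other:            # degenerate all-zero distances
                    cand = (other + 1) % n
                medoids[j] = cand
                logger.warning("cluster %d emptied; re-seeded with beat %d", j, cand)
            else:
                medoids[j] = _update_medoid(D, members)
        new_labels = _assign(D, medoids)
        # a medoid always belongs to its own cluster, even under distance ties
        for j in range(K):
            new_labels[medoids[j]] = j
        trace.append(float(sum(D[medoids[j], new_labels == j].sum() for j in range(K))))
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels

    # cluster 1 = higher mean heart rate
    hr = bs.hr
    mean_hr = [hr[labels == j].mean() if np.any(labels == j) else -np.inf
               for j in range(K)]
    order = np.argsort(mean_hr)[::-1]          # index of cluster becoming "1"
    final = np.empty(n, dtype=int)
    for new_j, old_j in enumerate(order):
        final[labels == old_j] = new_j + 1
    m1, m2 = int(medoids[order[0]]), int(medoids[order[1]])

    return ClusterResult(
        labels=final,
        medoid_index_1=m1,
        medoid_index_2=m2,
        C1=waveforms[m1],
        C2=waveforms[m2],
        n1=int(np.sum(final == 1)),
        n2=int(np.sum(final == 2)),
        iterations=it,
        converged=converged,
        seed=seed,
        objective_trace=trace,
    )


# -------------------------------------------------- phase association

def cross_tabulate_phase(
    cr: ClusterResult, gt_phases: list[str]
) -> tuple[pd.DataFrame, float]:
    """2x4 contingency of cluster label vs respiratory phase.

    The association score is the fraction of beats whose cluster matches
    the inspiration/expiration regime mapping (cluster 1 on the
    inspiratory phases), maximized over the two label permutations so the
    score does not depend on which cluster the algorithm called "1".
    """
    if len(gt_phases) != len(cr.labels):
        raise ValueError("labels and phases must be aligned per beat")
    phases = pd.Categorical(
        gt_phases, categories=["LLV-INS", "HLV-INS", "HLV-EXP", "LLV-EXP"]
    )
    table = pd.crosstab(
        pd.Series(cr.labels, name="cluster"),
        pd.Series(phases, name="phase"),
        dropna=False,
    )
    table = table.reindex(index=[1, 2], columns=phases.categories, fill_value=0)
    regime1 = np.array([p in REGIME1_PHASES for p in gt_phases])
    match = np.mean((cr.labels == 1) == regime1)
    score = float(max(match, 1.0 - match))
    return table, score
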