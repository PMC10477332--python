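"""Maximal information coefficient (MIC) estimation.

MIC of a paired sample is the maximum, over all X-by-Y grids whose cell count
is bounded by a budget ``B = n**0.6``, of the grid mutual information
normalized by ``log2(min(X, Y))``. The search over grids follows the
characteristic-matrix approximation: one axis is equipartitioned into q bins,
the partition of the other axis is optimized exactly by dynamic programming
over "clumps" (maximal runs of points that cannot profitably be split), and
the maximum is taken over both axis orientations and all admissible (q, l)
shapes. An exhaustive enumeration oracle is provided for tiny samples.

All logarithms are base 2, so every returned value lies in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .containers import FeatureMatrix

_NEG = -1e300


@dataclass(frozen=True)
class MicConfig:
    """Estimator settings.

    Attributes
    ----------
    B_exponent : float
        Grid budget exponent; the cell-count budget is ``B = n**B_exponent``
        (0.6 is the standard recommendation).
    clump_factor : int
        Superclump cap multiplier: the DP merges clumps down to at most
        ``clump_factor * l_max`` superclumps, trading exactness for speed on
        long, noisy sequences. Rarely triggered below a few hundred points.
    estimator : str
        ``"dp_approx"`` (default) or ``"exhaustive"`` (tiny n only).
    """

    B_exponent: float = 0.6
    clump_factor: int = 15
    estimator: str = "dp_approx"

    def __post_init__(self) -> None:
        if not 0.0 < self.B_exponent < 1.0:
            raise ValueError("B_exponent must lie in (0, 1)")
        if self.estimator not in ("dp_approx", "exhaustive"):
            raise ValueError("estimator must be 'dp_approx' or 'exhaustive'")


@dataclass(frozen=True)
class MicResult:
    """MIC value with the attaining grid shape and its mutual information."""

    value: float
    best_grid: tuple[int, int]  # (x bins, y bins)
    mutual_information: float   # bits
    degenerate: bool = False


def _effective_budget(n: int, exponent: float) -> int:
    # Strict X*Y < B with B = floor(n**0.6) would exclude even a 2x2 grid for
    # tiny n; the 2x2 grid is always admitted.
    return max(int(np.floor(n ** exponent)), 5)


def _equipartition(run_sizes: np.ndarray, q: int) -> np.ndarray:
    """Assign sorted-value runs to at most q rows of near-equal point count.

    Tied values are never split across rows. Returns the row index per run.
    """
    n = int(run_sizes.sum())
    rows = np.empty(len(run_sizes), dtype=np.int64)
    row, row_size, assigned = 0, 0, 0
    desired = n / q
    for i, s in enumerate(run_sizes):
        s = int(s)
        if (row_size > 0 and row < q - 1
                and abs(row_size + s - desired) >= abs(row_size - desired)):
            row += 1
            row_size = 0
            desired = (n - assigned) / (q - row)
        rows[i] = row
        row_size += s
        assigned += s
    return rows


@numba.njit(cache=False)
def _dp_optimize(cum: np.ndarray, n_total: int, l_max: int, h_q: float,
                 q_eff: int) -> tuple[float, int, float]:
    """Maximize normalized MI over clump-respecting column partitions.

    ``cum`` holds cumulative per-row counts for clump prefixes, shape
    (k+1, q). For each column count l in 2..l_max the DP finds the partition
    of the k clumps into exactly l columns maximizing
    ``sum_cols [-n_c log2 n_c + sum_rows n_cr log2 n_cr]``; the grid MI is
    ``H(rows) + S/n`` and is normalized by ``log2(min(q_eff, l))``.
    Returns (best normalized value, best l, its MI).
    """
    k = cum.shape[0] - 1
    q = cum.shape[1]
    log2 = np.log(2.0)

    # g[s, t] contributions are computed on demand from cum.
    def _g(s, t):
        c = 0.0
        acc = 0.0
        for r in range(q):
            nr = cum[t, r] - cum[s, r]
            c += nr
            if nr > 0:
                acc += nr * np.log(nr) / log2
        if c > 0:
            acc -= c * np.log(c) / log2
        return acc

    s_prev = np.full(k + 1, _NEG)
    for t in range(1, k + 1):
        s_prev[t] = _g(0, t)

    best_val = 0.0
    best_l = 2
    best_mi = 0.0
    for l in range(2, l_max + 1):
        s_curr = np.full(k + 1, _NEG)
        for t in range(l, k + 1):
            best = _NEG
            for s in range(l - 1, t):
                if s_prev[s] <= _NEG / 2:
                    continue
                v = s_prev[s] + _g(s, t)
                if v > best:
                    best = v
            s_curr[t] = best
        if s_curr[k] > _NEG / 2:
            mi = h_q + s_curr[k] / n_total
            denom = np.log(min(q_eff, l)) / log2
            if denom > 0:
                val = mi / denom
                if val > best_val:
                    best_val = val
                    best_l = l
                    best_mi = mi
        s_prev = s_curr
    return best_val, best_l, best_mi


def _runs(sorted_vals: np.ndarray) -> np.ndarray:
    """Sizes of maximal equal-value runs of a sorted array."""
    if sorted_vals.size == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(sorted_vals) != 0)
    bounds = np.concatenate(([0], change + 1, [sorted_vals.size]))
    return np.diff(bounds).astype(np.int64)


def _clump_counts(x: np.ndarray, row_of_point: np.ndarray,
                  q: int) -> np.ndarray:
    """Clump-by-row count matrix along the x axis.

    Points are sorted by x; equal-x points are atomic; adjacent atomic groups
    whose points all fall in one common row are merged (cutting inside such a
    run can never improve the optimum).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rows = row_of_point[order]
    n = xs.size
    change = np.flatnonzero(np.diff(xs) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))

    clumps: list[np.ndarray] = []
    cur = None
    cur_pure = -2  # row index if the running clump is single-row, else -1
    for a, b in zip(starts, ends):
        counts = np.bincount(rows[a:b], minlength=q).astype(np.int64)
        nz = np.flatnonzero(counts)
        pure = int(nz[0]) if nz.size == 1 else -1
        if cur is None:
            cur, cur_pure = counts, pure
        elif cur_pure >= 0 and pure == cur_pure:
            cur = cur + counts
        else:
            clumps.append(cur)
            cur, cur_pure = counts, pure
    clumps.append(cur)
    return np.vstack(clumps)


def _superclump(counts: np.ndarray, cap: int) -> np.ndarray:
    """Merge clumps down to at most ``cap`` near-equal-mass superclumps."""
    k = counts.shape[0]
    if k <= cap:
        return counts
    sizes = counts.sum(axis=1)
    groups = _equipartition(sizes, cap)
    merged = np.zeros((groups[-1] + 1, counts.shape[1]), dtype=np.int64)
    for i, g in enumerate(groups):
        merged[g] += counts[i]
    return merged


def _best_orientation(x: np.ndarray, y: np.ndarray, budget: int,
                      clump_factor: int) -> tuple[float, tuple[int, int], float]:
    """Best normalized MI equipartitioning y into rows, optimizing x columns."""
    n = x.size
    ys = np.sort(y)
    run_sizes = _runs(ys)
    n_distinct = run_sizes.size
    # map each point to its run index via rank in the sorted order
    order = np.argsort(y, kind="stable")
    run_of_sorted = np.repeat(np.arange(n_distinct), run_sizes)
    run_of_point = np.empty(n, dtype=np.int64)
    run_of_point[order] = run_of_sorted

    best = (0.0, (2, 2), 0.0)
    q_hi = min((budget - 1) // 2, n_distinct)
    for q in range(2, q_hi + 1):
        row_of_run = _equipartition(run_sizes, q)
        row_of_point = row_of_run[run_of_point]
        row_totals = np.bincount(row_of_point, minlength=q)
        q_eff = int(np.count_nonzero(row_totals))
        if q_eff < 2 or q_eff < q:
            # fewer usable rows than requested: identical to a smaller q
            continue
        p = row_totals[row_totals > 0] / n
        h_q = float(-(p * np.log2(p)).sum())
        l_max = (budget - 1) // q
        if l_max < 2:
            continue
        counts = _clump_counts(x, row_of_point, q)
        counts = _superclump(counts, max(clump_factor * l_max, 2 * l_max))
        cum = np.vstack([np.zeros((1, q), dtype=np.int64),
                         np.cumsum(counts, axis=0)])
        val, l, mi = _dp_optimize(cum.astype(np.float64), n, l_max, h_q,
                                  q_eff)
        if val > best[0]:
            best = (val, (l, q_eff), mi)
    return best


def compute_mic(x: np.ndarray, y: np.ndarray,
                config: MicConfig | None = None) -> MicResult:
    """MIC between two equal-length numeric sequences.

    Searches grids with ``X * Y < B`` (the 2x2 grid is always admitted) via
    the equipartition + dynamic-programming approximation, in both axis
    orientations, and returns the best normalized mutual information. A
    constant sequence yields value 0 with ``degenerate=True``.
    """
    config = config or MicConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 8:
        raise ValueError("MIC needs at least 8 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return MicResult(0.0, (1, 1), 0.0, degenerate=True)
    budget = _effective_budget(n, config.B_exponent)
    if config.estimator == "exhaustive":
        return mic_exhaustive(x, y, budget)

    v1, (l1, q1), mi1 = _best_orientation(x, y, budget, config.clump_factor)
    v2, (l2, q2), mi2 = _best_orientation(y, x, budget, config.clump_factor)
    if v2 > v1:
        return MicResult(min(v2, 1.0), (q2, l2), mi2)
    return MicResult(min(v1, 1.0), (l1, q1), mi1)


def _partitions(values: np.ndarray, n_bins: int):
    """Yield bin-index assignments over cut positions between distinct values."""
    from itertools import combinations

    distinct = np.unique(values)
    d = distinct.size
    if n_bins > d:
        return
    # ranks of each point among distinct values
    rank = np.searchsorted(distinct, values)
    for cuts in combinations(range(1, d), n_bins - 1):
        bins = np.zeros(values.size, dtype=np.int64)
        for c in cuts:
            bins += rank >= c
        yield bins


def mic_exhaustive(x: np.ndarray, y: np.ndarray, B: float) -> MicResult:
    """Exact MIC by enumerating every admissible grid (testing oracle).

    Feasible only for very small samples (n <= 14): all cut-point subsets on
    both axes are enumerated for every shape with ``X * Y < B`` (2x2 always
    admitted) and the maximum normalized mutual information is returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n > 14:
        raise ValueError("exhaustive MIC enumeration is limited to n <= 14")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return MicResult(0.0, (1, 1), 0.0, degenerate=True)
    budget = max(int(np.floor(B)), 5)
    best = (0.0, (2, 2), 0.0)
    for nx in range(2, n + 1):
        for ny in range(2, n + 1):
            if nx * ny >= budget:
                continue
            denom = np.log2(min(nx, ny))
            for bx in _partitions(x, nx):
                for by in _partitions(y, ny):
                    mi = _grid_mi(bx, by, nx, ny)
                    val = mi / denom
                    if val > best[0]:
                        best = (val, (nx, ny), mi)
    return MicResult(min(best[0], 1.0), best[1], best[2])


def _grid_mi(bx: np.ndarray, by: np.ndarray, nx: int, ny: int) -> float:
    n = bx.size
    joint = np.zeros((nx, ny))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nzx, nzy = np.nonzero(joint)
    p = joint[nzx, nzy]
    return float(np.sum(p * np.log2(p / (px[nzx] * py[nzy]))))


def relevance_scores(F: FeatureMatrix,
                     config: MicConfig | None = None) -> np.ndarray:
    """MIC of every feature column against the class label, order preserved."""
    if np.unique(F.labels).size < 2:
        raise ValueError("relevance scores require at least 2 classes")
    y = F.labels.astype(float)
    return np.array([compute_mic(F.values[:, j], y, config).value
                     for j in range(F.n_features)])
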