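"""MIC_e and TIC_e estimators.

The maximal information coefficient (MIC) of two real variables is the
maximum, over grid resolutions (k, l) with k*l <= B, of the mutual
information of the best k-by-l grid discretization, normalized by
log2(min(k, l)).  The efficient estimator computed here (MIC_e)
equipartitions one axis into l mass-balanced rows and optimizes the
other axis into at most k columns with a dynamic program over clump
boundaries; the larger of the two axis orientations is kept.  TIC_e is
the sum of all characteristic-matrix entries and serves as a high-power
test statistic against independence.

Both statistics depend on the data only through rank order, so they are
exactly invariant under strictly increasing transforms of either
variable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import _entries_pair, _mic_tic_pair, _stats_batch

__all__ = [
    "MineParams",
    "CharacteristicMatrix",
    "MineResult",
    "grid_bound",
    "equipartition",
    "equicharclump",
    "optimize_axis",
    "characteristic_matrix",
    "mic_e",
    "tic_e",
]


@dataclass(frozen=True)
class MineParams:
    """Estimator parameters.

    b : maximal grid resolution; entries exist for k*l <= b (b >= 4).
        The default 9 is tuned for power in the independence test; the
        strength stage instead uses the sample-size-dependent bound
        ``grid_bound(n, alpha_for_n(n))``.
    c : clumping coarseness factor (>= 1); the optimized axis is reduced
        to at most c*k candidate cut intervals before the grid search.
    """

    b: int = 9
    c: int = 5

    def __post_init__(self) -> None:
        if int(self.b) != self.b or self.b < 4:
            raise ValueError(f"b must be an integer >= 4, got {self.b}")
        if int(self.c) != self.c or self.c < 1:
            raise ValueError(f"c must be an integer >= 1, got {self.c}")


@dataclass(frozen=True)
class CharacteristicMatrix:
    """Normalized-MI entries M[(k, l)] for all k, l >= 2 with k*l <= b."""

    entries: dict
    params: MineParams
    n: int

    @property
    def mic(self) -> float:
        return max(self.entries.values())

    @property
    def tic(self) -> float:
        return float(sum(self.entries.values()))


@dataclass(frozen=True)
class MineResult:
    mic_e: float
    tic_e: float
    params: MineParams
    n: int


def grid_bound(n: int, alpha: float, b_min: int = 4) -> int:
    """Sample-size-dependent grid bound B(n) = max(floor(n^alpha), b_min)."""
    if n < 2:
        raise ValueError(f"need at least 2 samples, got n={n}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return max(int(math.floor(n ** alpha + 1e-9)), b_min)


def _rank_groups(values: np.ndarray):
    """Stable sort order and tie-group encoding of a 1-D array.

    Returns (groups, n_groups, order): ``groups[i]`` is the 0-based index
    of point i's tie group in ascending value order; ``order`` sorts the
    points ascending (stable).
    """
    order = np.argsort(values, kind="stable").astype(np.int64)
    sv = values[order]
    boundary = np.empty(len(values), dtype=np.int64)
    boundary[0] = 0
    if len(values) > 1:
        boundary[1:] = (sv[1:] != sv[:-1]).astype(np.int64)
    gid_sorted = np.cumsum(boundary)
    groups = np.empty(len(values), dtype=np.int64)
    groups[order] = gid_sorted
    return groups, int(gid_sorted[-1]) + 1, order


def prepare_rank_matrix(arr: np.ndarray):
    """Per-row rank encodings for a variables-by-samples matrix.

    Returns (G, NG, O) suitable for the batch kernels: group ids,
    group counts and stable sort orders, one row per variable.
    """
    arr = np.asarray(arr, dtype=np.float64)
    m, n = arr.shape
    G = np.empty((m, n), dtype=np.int64)
    NG = np.empty(m, dtype=np.int64)
    O = np.empty((m, n), dtype=np.int64)
    for i in range(m):
        G[i], NG[i], O[i] = _rank_groups(arr[i])
    return G, NG, O


def _validate_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 5:
        raise ValueError(f"need at least 5 samples, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(
            "constant input vector: all characteristic entries are 0",
            stacklevel=3,
        )
    return x, y


def equipartition(values, l: int) -> np.ndarray:
    """Assign each point to one of l mass-balanced rows.

    Points with equal value always share a row; when n is not divisible
    by l the extra points go to the lowest-index rows.  Returns the row
    index (0-based) per point, aligned with the input order.  If there
    are fewer distinct values than rows, the trailing rows stay empty
    (degenerate partition; handled, not fatal).
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if l < 2:
        raise ValueError(f"need l >= 2 rows, got {l}")
    if n < l:
        raise ValueError(f"need at least {l} points, got {n}")
    groups, n_groups, order = _rank_groups(values)
    counts = np.bincount(groups, minlength=n_groups)
    base, rem = divmod(n, l)
    row_of_group = np.empty(n_groups, dtype=np.int64)
    cur = 0
    cnt = 0
    for g in range(n_groups):
        row_of_group[g] = cur
        cnt += counts[g]
        target = base + 1 if cur < rem else base
        if cnt >= target and cur < l - 1:
            cur += 1
            cnt = 0
    return row_of_group[groups]


def equicharclump(x, rows, max_clumps: int) -> np.ndarray:
    """Candidate column cut-points along x for a fixed row assignment.

    Scanning the points in x order (ties atomic), consecutive points
    sharing a single row label are merged into one clump; if more than
    ``max_clumps`` clumps result, they are greedily coarsened into at
    most ``max_clumps`` superclumps of near-equal point mass, never
    splitting a natural clump.  Returns the ascending cumulative point
    counts at clump ends (the last entry is n).
    """
    x = np.asarray(x, dtype=np.float64)
    rows = np.asarray(rows)
    n = len(x)
    gx, _, order = _rank_groups(x)
    row_sorted = rows[order]
    gx_sorted = gx[order]

    sizes = []
    i = 0
    prev_uniform = False
    prev_row = -1
    while i < n:
        j = i
        g = gx_sorted[i]
        r0 = row_sorted[i]
        uniform = True
        while j < n and gx_sorted[j] == g:
            if row_sorted[j] != r0:
                uniform = False
            j += 1
        if sizes and uniform and prev_uniform and r0 == prev_row:
            sizes[-1] += j - i
        else:
            sizes.append(j - i)
        prev_uniform = uniform
        prev_row = r0 if uniform else -1
        i = j

    if len(sizes) > max_clumps:
        target = -(-n // max_clumps)  # ceil
        merged = []
        mass = 0
        for s in sizes:
            mass += s
            if mass >= target:
                merged.append(mass)
                mass = 0
        if mass > 0:
            merged.append(mass)
        sizes = merged
    return np.cumsum(np.asarray(sizes, dtype=np.int64))


def optimize_axis(x, rows, k_max: int, boundaries=None) -> np.ndarray:
    """I*(k) for k = 2..k_max: max MI over <= k contiguous columns.

    Plain-Python dynamic program over the clump prefixes; the compiled
    kernel used by :func:`characteristic_matrix` implements the same
    recurrence.  ``boundaries`` defaults to the natural clumps of
    (x, rows) without coarsening.
    """
    if k_max < 2:
        raise ValueError(f"need k_max >= 2, got {k_max}")
    x = np.asarray(x, dtype=np.float64)
    rows = np.asarray(rows, dtype=np.int64)
    n = len(x)
    if boundaries is None:
        boundaries = equicharclump(x, rows, max_clumps=n)
    boundaries = np.asarray(boundaries, dtype=np.int64)
    order = np.argsort(x, kind="stable")
    row_sorted = rows[order]
    l = int(rows.max()) + 1
    nc = len(boundaries)

    cumrow = np.zeros((nc + 1, l))
    start = 0
    for t, end in enumerate(boundaries, start=1):
        cumrow[t] = cumrow[t - 1] + np.bincount(
            row_sorted[start:end], minlength=l
        )
        start = end
    cumcnt = np.concatenate([[0], boundaries]).astype(float)

    def nlog2n(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        pos = v > 0
        out[pos] = v[pos] * np.log2(v[pos])
        return out

    def term(s, t):
        return float(
            nlog2n(cumrow[t] - cumrow[s]).sum()
            - nlog2n(cumcnt[t] - cumcnt[s]).sum()
        )

    prow = cumrow[nc] / n
    hq = float(-nlog2n(prow).sum())

    NEG = -math.inf
    prev = [NEG] * (nc + 1)
    for t in range(1, nc + 1):
        prev[t] = term(0, t)
    best = {1: prev[nc]}
    for m in range(2, k_max + 1):
        if nc < m:
            break
        curv = [NEG] * (nc + 1)
        for t in range(m, nc + 1):
            curv[t] = max(prev[s] + term(s, t) for s in range(m - 1, t))
        best[m] = curv[nc]
        prev = curv

    out = np.empty(k_max - 1)
    run = 0.0
    for k in range(2, k_max + 1):
        if k in best and best[k] > NEG:
            run = max(run, hq + best[k] / n)
        out[k - 2] = run
    return out


def characteristic_matrix(x, y, params: MineParams = MineParams()):
    """All normalized-MI entries M[(k, l)], k, l >= 2, k*l <= params.b.

    Entry (k, l) equipartitions one axis into l bins and DP-optimizes
    the other into at most k bins, takes the larger of the two axis
    orientations, and normalizes by log2(min(k, l)).
    """
    x, y = _validate_pair(x, y)
    gx, ngx, ox = _rank_groups(x)
    gy, ngy, oy = _rank_groups(y)
    ent = _entries_pair(gx, ngx, ox, gy, ngy, oy, len(x), params.b, params.c)
    entries = {}
    for l in range(2, params.b // 2 + 1):
        for k in range(2, params.b // l + 1):
            entries[(k, l)] = float(ent[k, l])
    return CharacteristicMatrix(entries=entries, params=params, n=len(x))


def _mic_tic(x, y, params):
    x, y = _validate_pair(x, y)
    gx, ngx, ox = _rank_groups(x)
    gy, ngy, oy = _rank_groups(y)
    return _mic_tic_pair(gx, ngx, ox, gy, ngy, oy, len(x), params.b, params.c)


def mic_e(x, y, params: MineParams = MineParams()) -> float:
    """Maximum characteristic-matrix entry; in [0, 1], symmetric in (x, y)."""
    return float(_mic_tic(x, y, params)[0])


def tic_e(x, y, params: MineParams = MineParams()) -> float:
    """Sum of all characteristic-matrix entries (unnormalized)."""
    return float(_mic_tic(x, y, params)[1])


def mine(x, y, params: MineParams = MineParams()) -> MineResult:
    """Both statistics in one pass."""
    x = np.asarray(x, dtype=np.float64)
    m, t = _mic_tic(x, y, params)
    return MineResult(mic_e=float(m), tic_e=float(t), params=params, n=len(x))


def stats_many(GX, NGX, OX, GY, NGY, OY, ix, iy, params: MineParams):
    """Batch MIC_e/TIC_e over pre-ranked matrices (see prepare_rank_matrix)."""
    ix = np.asarray(ix, dtype=np.int64)
    iy = np.asarray(iy, dtype=np.int64)
    out_mic = np.empty(len(ix))
    out_tic = np.empty(len(ix))
    _stats_batch(GX, NGX, OX, GY, NGY, OY, ix, iy, params.b, params.c,
                 out_mic, out_tic)
    return out_mic, out_tic
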