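"""Independent brute-force oracle for the characteristic matrix.

Recomputes MIC_e/TIC_e on tiny inputs by exhaustive enumeration: for
each grid size (k, l) and each axis orientation, the equipartitioned
axis is split by the same mass-balance rule as the estimator definition
(ties atomic, remainder to low rows) and the optimized axis is searched
over ALL placements of at most k-1 cuts in the gaps between distinct
values.  No clumping, no dynamic programming: every admissible grid is
scored directly from its joint counts.
"""

from itertools import combinations

import numpy as np


def brute_equipartition(values, l):
    """Mass-balanced row per point; ties atomic, remainder to low rows."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    rows = np.empty(n, dtype=int)
    base, rem = divmod(n, l)
    cur = cnt = 0
    i = 0
    sv = values[order]
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        rows[order[i:j]] = cur
        cnt += j - i
        target = base + 1 if cur < rem else base
        if cnt >= target and cur < l - 1:
            cur += 1
            cnt = 0
        i = j
    return rows


def _mi(cols, rows):
    """Mutual information (bits) of two integer label vectors."""
    n = len(cols)
    joint = np.zeros((cols.max() + 1, rows.max() + 1))
    for a, b in zip(cols, rows):
        joint[a, b] += 1
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _best_mi_over_cuts(opt_values, rows, k):
    """Max MI over all partitions of opt_values into <= k ordered bins."""
    opt_values = np.asarray(opt_values, dtype=float)
    n = len(opt_values)
    order = np.argsort(opt_values, kind="stable")
    sv = opt_values[order]
    rows_sorted = np.asarray(rows)[order]
    gaps = [i for i in range(1, n) if sv[i] != sv[i - 1]]
    best = 0.0
    for m in range(0, k):  # m cuts -> m+1 columns
        for cuts in combinations(gaps, m):
            cols = np.zeros(n, dtype=int)
            for c in cuts:
                cols[c:] += 1
            best = max(best, _mi(cols, rows_sorted))
    return best


def oracle_char_matrix(x, y, B):
    """Every entry M[(k, l)] by exhaustive search; both orientations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    entries = {}
    for l in range(2, B // 2 + 1):
        rows_y = brute_equipartition(y, l)
        rows_x = brute_equipartition(x, l)
        for k in range(2, B // l + 1):
            a = _best_mi_over_cuts(x, rows_y, k)
            b = _best_mi_over_cuts(y, rows_x, k)
            entries[(k, l)] = min(max(a, b) / np.log2(min(k, l)), 1.0)
    return entries


def oracle_mic_tic(x, y, B):
    ent = oracle_char_matrix(x, y, B)
    return max(ent.values()), sum(ent.values())
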