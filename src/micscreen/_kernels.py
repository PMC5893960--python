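"""Compiled kernels for the characteristic-matrix grid search.

Everything here operates on integer rank/group encodings of the two
variables, so the statistics depend on the data only through rank order.
Each point i carries a *group id* per axis (points with equal values share
a group; group ids increase with the value) and each axis has a stable
sort order of the point indices.

The per-orientation work for one (pair, l) is:

  1. equipartition the "row" axis into l mass-balanced rows (tie groups
     are atomic; remainders go to the lowest-index rows),
  2. scan the other axis in sorted order and merge runs of points that
     share a single row into clumps; coarsen to at most c*kmax
     superclumps of near-equal mass when there are more,
  3. a dynamic program over clump prefixes that yields, for every
     k <= kmax = B // l, the maximum mutual information achievable by
     any partition of the clumps into at most k contiguous columns.

The DP state is the unnormalized quantity
    sum_{j,q} n_jq*log2(n_jq) - sum_j n_j*log2(n_j),
which is additive over columns; I(P;Q) = H(Q) + state/n.
"""

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def _nlog2n(v):
    # v * log2(v) with the 0*log(0) := 0 convention
    if v <= 0.0:
        return 0.0
    return v * np.log2(v)


@njit(cache=True)
def _axis_profiles(ge, n_ge, order_o, go, n, B, c, out):
    """Fill out[l, k] with I*(k | l rows) for 2 <= l <= B//2, 2 <= k <= B//l.

    ge:      group id per point on the equipartitioned axis
    n_ge:    number of groups on that axis
    order_o: point indices sorted by the optimized axis (stable)
    go:      group id per point on the optimized axis
    """
    lmax = B // 2
    counts_e = np.zeros(n_ge, np.int64)
    for i in range(n):
        counts_e[ge[i]] += 1

    row_of_group = np.empty(n_ge, np.int64)
    row_pt = np.empty(n, np.int64)
    clump_of = np.empty(n, np.int64)

    for l in range(2, lmax + 1):
        kmax = B // l

        # --- equipartition: tie groups atomic, remainder to low rows ---
        base = n // l
        rem = n % l
        cur = 0
        cnt = 0
        for g in range(n_ge):
            row_of_group[g] = cur
            cnt += counts_e[g]
            target = base + 1 if cur < rem else base
            if cnt >= target and cur < l - 1:
                cur += 1
                cnt = 0

        nrow = np.zeros(l, np.float64)
        for i in range(n):
            r = row_of_group[ge[i]]
            row_pt[i] = r
            nrow[r] += 1.0
        hq = 0.0
        for r in range(l):
            if nrow[r] > 0.0:
                hq -= _nlog2n(nrow[r] / n)

        # --- natural clumps along the optimized axis ---
        # merge consecutive tie groups whose points all lie in one and the
        # same row; a tie group spanning several rows is its own clump
        cid = -1
        prev_uniform = False
        prev_row = -1
        i = 0
        while i < n:
            g = go[order_o[i]]
            r0 = row_pt[order_o[i]]
            uniform = True
            j = i
            while j < n and go[order_o[j]] == g:
                if row_pt[order_o[j]] != r0:
                    uniform = False
                j += 1
            if not (cid >= 0 and uniform and prev_uniform and r0 == prev_row):
                cid += 1
            for t in range(i, j):
                clump_of[t] = cid
            prev_uniform = uniform
            prev_row = r0 if uniform else -1
            i = j
        nclump = cid + 1

        # --- superclump coarsening to at most c*kmax clumps ---
        max_clumps = c * kmax
        if nclump > max_clumps:
            target_mass = (n + max_clumps - 1) // max_clumps
            sid = 0
            mass = 0
            i = 0
            while i < n:
                ccur = clump_of[i]
                j = i
                while j < n and clump_of[j] == ccur:
                    j += 1
                for t in range(i, j):
                    clump_of[t] = sid
                mass += j - i
                if mass >= target_mass:
                    sid += 1
                    mass = 0
                i = j
            nclump = sid + 1 if mass > 0 else sid

        # --- cumulative counts over clump prefixes ---
        cumcnt = np.zeros(nclump + 1, np.float64)
        cumrow = np.zeros((nclump + 1, l), np.float64)
        for pos in range(n):
            t = clump_of[pos] + 1
            cumcnt[t] += 1.0
            cumrow[t, row_pt[order_o[pos]]] += 1.0
        for t in range(1, nclump + 1):
            cumcnt[t] += cumcnt[t - 1]
            for r in range(l):
                cumrow[t, r] += cumrow[t - 1, r]

        # --- DP over clump prefixes ---
        prev = np.empty(nclump + 1, np.float64)
        curv = np.empty(nclump + 1, np.float64)
        best = np.full(kmax + 1, NEG_INF)
        for t in range(1, nclump + 1):
            term = -_nlog2n(cumcnt[t])
            for r in range(l):
                term += _nlog2n(cumrow[t, r])
            prev[t] = term
        best[1] = prev[nclump]
        for m in range(2, kmax + 1):
            if nclump < m:
                break
            for t in range(m, nclump + 1):
                bv = NEG_INF
                for s in range(m - 1, t):
                    ncol = cumcnt[t] - cumcnt[s]
                    term = -_nlog2n(ncol)
                    for r in range(l):
                        term += _nlog2n(cumrow[t, r] - cumrow[s, r])
                    v = prev[s] + term
                    if v > bv:
                        bv = v
                curv[t] = bv
            best[m] = curv[nclump]
            tmp = prev
            prev = curv
            curv = tmp

        # I*(k) = max over <= k columns; one column gives I = 0
        run = 0.0
        for k in range(2, kmax + 1):
            if best[k] > NEG_INF / 2:
                v = hq + best[k] / n
                if v > run:
                    run = v
            out[l, k] = run


@njit(cache=True)
def _entries_pair(gx, n_gx, ox, gy, n_gy, oy, n, B, c):
    """Characteristic-matrix entries for one pair.

    Returns ent[k, l] = normalized MI for every k, l >= 2 with k*l <= B
    (k: optimized-axis bins, l: equipartitioned-axis bins; max over the
    two axis orientations), and -1 outside the admissible set.
    """
    lmax = B // 2
    prof_a = np.zeros((lmax + 1, lmax + 1), np.float64)  # equip y, opt x
    prof_b = np.zeros((lmax + 1, lmax + 1), np.float64)  # equip x, opt y
    _axis_profiles(gy, n_gy, ox, gx, n, B, c, prof_a)
    _axis_profiles(gx, n_gx, oy, gy, n, B, c, prof_b)
    ent = np.full((lmax + 1, lmax + 1), -1.0)
    for l in range(2, lmax + 1):
        for k in range(2, B // l + 1):
            v = prof_a[l, k]
            if prof_b[l, k] > v:
                v = prof_b[l, k]
            v /= np.log2(min(k, l))
            if v > 1.0:
                v = 1.0
            ent[k, l] = v
    return ent


@njit(cache=True)
def _mic_tic_pair(gx, n_gx, ox, gy, n_gy, oy, n, B, c):
    ent = _entries_pair(gx, n_gx, ox, gy, n_gy, oy, n, B, c)
    lmax = B // 2
    mic = 0.0
    tic = 0.0
    for l in range(2, lmax + 1):
        for k in range(2, B // l + 1):
            v = ent[k, l]
            if v > mic:
                mic = v
            tic += v
    return mic, tic


@njit(cache=True)
def _stats_batch(GX, NGX, OX, GY, NGY, OY, ix, iy, B, c, out_mic, out_tic):
    """MIC_e/TIC_e for many pairs given pre-ranked variable matrices."""
    n = GX.shape[1]
    for p in range(ix.shape[0]):
        a = ix[p]
        b = iy[p]
        mic, tic = _mic_tic_pair(
            GX[a], NGX[a], OX[a], GY[b], NGY[b], OY[b], n, B, c
        )
        out_mic[p] = mic
        out_tic[p] = tic


@njit(cache=True)
def _tic_null_batch(perms, B, c, out):
    """Null TIC_e for permutations of tie-free rank sequences.

    x is the identity rank sequence 0..n-1; row r of `perms` is the
    permuted y. Group ids equal the rank values themselves.
    """
    R, n = perms.shape
    gx = np.arange(n)
    ox = np.arange(n)
    ngx = n
    inv = np.empty(n, np.int64)
    for r in range(R):
        pr = perms[r]
        for i in range(n):
            inv[pr[i]] = i
        _mic, tic = _mic_tic_pair(gx, ngx, ox, pr, n, inv, n, B, c)
        out[r] = tic
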