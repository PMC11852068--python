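"""Numba kernels for greedy Surprise / modularity community detection.

The 100-tier threshold sweep scores every (trial, window) adjacency matrix at
every threshold, which amounts to hundreds of thousands of community
detections per band; these kernels keep that tractable on one CPU.

Both detectors share the same agglomerative scheme: start from singleton
communities and repeatedly apply the single community merge or single-node
relabel that most increases the objective, until no move improves it.  The
``seed`` argument fixes the candidate enumeration order, which is how ties
are broken, so results are deterministic given the seed.

Surprise is the (base-10) negative log of the cumulative hypergeometric tail
probability of observing at least the realized number of intra-community
edges when m edges are thrown uniformly over the M node pairs:

    S = -log10 sum_{j=m_int}^{min(m, M_int)} C(M_int, j) C(M-M_int, m-j) / C(M, m)

Pure-Python brute-force oracles in the test suite cross-check both detectors
and the Surprise value against exhaustive enumeration on small graphs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LN10 = math.log(10.0)


@njit(cache=True)
def _perm(n, seed):
    """Seeded Fisher-Yates permutation of 0..n-1 using a 64-bit LCG."""
    state = np.uint64(seed * 6364136223846793005 + 1442695040888963407)
    out = np.arange(n, dtype=np.int64)
    for i in range(n - 1, 0, -1):
        state = np.uint64(state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
        j = int(state >> np.uint64(33)) % (i + 1)
        tmp = out[i]
        out[i] = out[j]
        out[j] = tmp
    return out


@njit(cache=True)
def _log_comb(lgf, n, k):
    return lgf[n] - lgf[k] - lgf[n - k]


@njit(cache=True)
def _surprise_value(lgf, M, m, M_int, m_int):
    """S = -log10 P[X >= m_int], X ~ Hypergeom(M, M_int, m); 0 for trivial cases.

    The shorter of the upper tail and the complementary lower sum is
    evaluated (log-space with max-shift for the tail) for speed and
    stability; ``lgf[i]`` must hold ``lgamma(i + 1)``.
    """
    if m <= 0 or M_int <= 0 or m_int <= 0:
        return 0.0
    hi = m if m < M_int else M_int
    lo = m - (M - M_int)
    if lo < 0:
        lo = 0
    if m_int <= lo:
        return 0.0
    if m_int > hi:
        m_int = hi
    denom = _log_comb(lgf, M, m)
    n_tail = hi - m_int + 1
    n_low = m_int - lo
    if n_tail <= n_low:
        maxlog = -1.0e308
        for j in range(m_int, hi + 1):
            lt = _log_comb(lgf, M_int, j) + _log_comb(lgf, M - M_int, m - j) - denom
            if lt > maxlog:
                maxlog = lt
        acc = 0.0
        for j in range(m_int, hi + 1):
            lt = _log_comb(lgf, M_int, j) + _log_comb(lgf, M - M_int, m - j) - denom
            acc += math.exp(lt - maxlog)
        s = -(maxlog + math.log(acc)) / _LN10
    else:
        p_low = 0.0
        for j in range(lo, m_int):
            p_low += math.exp(
                _log_comb(lgf, M_int, j) + _log_comb(lgf, M - M_int, m - j) - denom
            )
        tail = 1.0 - p_low
        if tail < 1.0e-15:
            # The lower branch is only taken when it is the short side, i.e.
            # the tail is large; this guard is purely defensive.
            tail = 1.0e-15
        s = -math.log(tail) / _LN10
    if s < 0.0:
        s = 0.0
    return s


@njit(cache=True)
def _memo_surprise(memo, lgf, M, m, M_int, m_int):
    idx = M_int * (M + 1) + m_int
    v = memo[idx]
    if not np.isnan(v):
        return v
    v = _surprise_value(lgf, M, m, M_int, m_int)
    memo[idx] = v
    return v


@njit(cache=True)
def surprise_greedy(adj, seed, lgf):
    """Greedy Surprise maximization; returns (labels, S of the final partition)."""
    n = adj.shape[0]
    labels = np.arange(n, dtype=np.int64)
    M = n * (n - 1) // 2
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    if m == 0 or n == 1:
        return labels, 0.0
    size = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=np.uint8)
    e = np.zeros((n, n), dtype=np.int64)  # e[c, d]: edges between communities (intra on diagonal)
    kic = np.zeros((n, n), dtype=np.int64)  # kic[i, c]: edges from node i into community c
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                e[i, j] = 1
                kic[i, j] = 1
    m_int = 0
    M_int = 0
    s_cur = 0.0
    memo = np.full((M + 1) * (M + 1), np.nan)
    perm = _perm(n, seed)
    tol = 1.0e-12
    while True:
        best_gain = tol
        best_kind = -1
        best_a = -1
        best_b = -1
        best_mint = 0
        best_Mint = 0
        best_s = s_cur
        for ia in range(n):
            a = perm[ia]
            if active[a] == 0:
                continue
            for ib in range(ia + 1, n):
                b = perm[ib]
                if active[b] == 0:
                    continue
                nm = m_int + e[a, b]
                nM = M_int + size[a] * size[b]
                s_new = _memo_surprise(memo, lgf, M, m, nM, nm)
                if s_new - s_cur > best_gain:
                    best_gain = s_new - s_cur
                    best_kind = 0
                    best_a = a
                    best_b = b
                    best_mint = nm
                    best_Mint = nM
                    best_s = s_new
        for ii in range(n):
            i = perm[ii]
            c = labels[i]
            for idd in range(n):
                d = perm[idd]
                if d == c or active[d] == 0:
                    continue
                nm = m_int - kic[i, c] + kic[i, d]
                nM = M_int - (size[c] - 1) + size[d]
                s_new = _memo_surprise(memo, lgf, M, m, nM, nm)
                if s_new - s_cur > best_gain:
                    best_gain = s_new - s_cur
                    best_kind = 1
                    best_a = i
                    best_b = d
                    best_mint = nm
                    best_Mint = nM
                    best_s = s_new
        if best_kind < 0:
            break
        if best_kind == 0:
            a = best_a
            b = best_b
            e[a, a] += e[b, b] + e[a, b]
            for x in range(n):
                if x != a and x != b:
                    e[a, x] += e[b, x]
                    e[x, a] = e[a, x]
            e[a, b] = 0
            e[b, a] = 0
            for x in range(n):
                e[b, x] = 0
                e[x, b] = 0
            for i2 in range(n):
                kic[i2, a] += kic[i2, b]
                kic[i2, b] = 0
            size[a] += size[b]
            size[b] = 0
            active[b] = 0
            for i2 in range(n):
                if labels[i2] == b:
                    labels[i2] = a
        else:
            i = best_a
            d = best_b
            c = labels[i]
            kc = kic[i, c]
            kd = kic[i, d]
            for x in range(n):
                if active[x] == 0 or x == c or x == d:
                    continue
                kx = kic[i, x]
                if kx:
                    e[c, x] -= kx
                    e[x, c] = e[c, x]
                    e[d, x] += kx
                    e[x, d] = e[d, x]
            e[c, c] -= kc
            e[d, d] += kd
            ecd = e[c, d] + kc - kd
            e[c, d] = ecd
            e[d, c] = ecd
            for j2 in range(n):
                if adj[i, j2]:
                    kic[j2, c] -= 1
                    kic[j2, d] += 1
            size[c] -= 1
            size[d] += 1
            labels[i] = d
            if size[c] == 0:
                active[c] = 0
                for x in range(n):
                    e[c, x] = 0
                    e[x, c] = 0
        m_int = best_mint
        M_int = best_Mint
        s_cur = best_s
    return labels, s_cur


@njit(cache=True)
def modularity_greedy(adj, seed):
    """Greedy Newman modularity maximization; returns (labels, Q of the partition)."""
    n = adj.shape[0]
    labels = np.arange(n, dtype=np.int64)
    m = 0
    deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                deg[i] += 1
        # deg counts each incident edge once per endpoint
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                m += 1
    if m == 0 or n == 1:
        return labels, 0.0
    size = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=np.uint8)
    e = np.zeros((n, n), dtype=np.int64)
    kic = np.zeros((n, n), dtype=np.int64)
    dsum = deg.astype(np.float64)  # community degree sums
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                e[i, j] = 1
                kic[i, j] = 1
    two_m = 2.0 * m
    q_cur = 0.0
    for i in range(n):
        q_cur -= (deg[i] / two_m) ** 2
    perm = _perm(n, seed)
    tol = 1.0e-12
    while True:
        best_gain = tol
        best_kind = -1
        best_a = -1
        best_b = -1
        for ia in range(n):
            a = perm[ia]
            if active[a] == 0:
                continue
            for ib in range(ia + 1, n):
                b = perm[ib]
                if active[b] == 0:
                    continue
                gain = e[a, b] / m - dsum[a] * dsum[b] / (2.0 * m * m)
                if gain > best_gain:
                    best_gain = gain
                    best_kind = 0
                    best_a = a
                    best_b = b
        for ii in range(n):
            i = perm[ii]
            c = labels[i]
            for idd in range(n):
                d = perm[idd]
                if d == c or active[d] == 0:
                    continue
                gain = (kic[i, d] - kic[i, c]) / m - deg[i] * (
                    dsum[d] - dsum[c] + deg[i]
                ) / (2.0 * m * m)
                if gain > best_gain:
                    best_gain = gain
                    best_kind = 1
                    best_a = i
                    best_b = d
        if best_kind < 0:
            break
        if best_kind == 0:
            a = best_a
            b = best_b
            e[a, a] += e[b, b] + e[a, b]
            for x in range(n):
                if x != a and x != b:
                    e[a, x] += e[b, x]
                    e[x, a] = e[a, x]
            e[a, b] = 0
            e[b, a] = 0
            for x in range(n):
                e[b, x] = 0
                e[x, b] = 0
            for i2 in range(n):
                kic[i2, a] += kic[i2, b]
                kic[i2, b] = 0
            size[a] += size[b]
            size[b] = 0
            dsum[a] += dsum[b]
            dsum[b] = 0.0
            active[b] = 0
            for i2 in range(n):
                if labels[i2] == b:
                    labels[i2] = a
        else:
            i = best_a
            d = best_b
            c = labels[i]
            kc = kic[i, c]
            kd = kic[i, d]
            for x in range(n):
                if active[x] == 0 or x == c or x == d:
                    continue
                kx = kic[i, x]
                if kx:
                    e[c, x] -= kx
                    e[x, c] = e[c, x]
                    e[d, x] += kx
                    e[x, d] = e[d, x]
            e[c, c] -= kc
            e[d, d] += kd
            ecd = e[c, d] + kc - kd
            e[c, d] = ecd
            e[d, c] = ecd
            for j2 in range(n):
                if adj[i, j2]:
                    kic[j2, c] -= 1
                    kic[j2, d] += 1
            size[c] -= 1
            size[d] += 1
            dsum[c] -= deg[i]
            dsum[d] += deg[i]
            labels[i] = d
            if size[c] == 0:
                active[c] = 0
                for x in range(n):
                    e[c, x] = 0
                    e[x, c] = 0
        q_cur += best_gain
    return labels, q_cur


@njit(cache=True)
def lcc_fraction(adj):
    """Size of the largest connected component divided by n."""
    n = adj.shape[0]
    visited = np.zeros(n, dtype=np.uint8)
    stack = np.empty(n, dtype=np.int64)
    best = 1
    for s in range(n):
        if visited[s]:
            continue
        visited[s] = 1
        stack[0] = s
        top = 1
        count = 0
        while top > 0:
            top -= 1
            u = stack[top]
            count += 1
            for v in range(n):
                if adj[u, v] and visited[v] == 0:
                    visited[v] = 1
                    stack[top] = v
                    top += 1
        if count > best:
            best = count
    return best / n


@njit(cache=True)
def surprise_sweep(weights, taus, seed, lgf):
    """Sum of Surprise and LCC fraction over a batch of weight matrices per threshold.

    ``weights``: (n_matrices, n, n); ``taus`` ascending.  Returns
    ``(S_sums, lcc_sums)`` each of length ``len(taus)``; divide by the batch
    size for means.  Because edge sets are nested across ascending
    thresholds, a threshold that removes no edge reuses the previous result.
    """
    n_mat = weights.shape[0]
    n = weights.shape[1]
    n_tau = taus.size
    s_sums = np.zeros(n_tau)
    lcc_sums = np.zeros(n_tau)
    adj = np.zeros((n, n), dtype=np.uint8)
    for im in range(n_mat):
        w = weights[im]
        prev_m = -1
        prev_s = 0.0
        prev_lcc = 1.0
        for it in range(n_tau):
            tau = taus[it]
            mm = 0
            for i in range(n):
                for j in range(n):
                    if i != j and w[i, j] > tau:
                        adj[i, j] = 1
                    else:
                        adj[i, j] = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if adj[i, j]:
                        mm += 1
            if mm == prev_m:
                s_sums[it] += prev_s
                lcc_sums[it] += prev_lcc
                continue
            _, s_val = surprise_greedy(adj, seed, lgf)
            frac = lcc_fraction(adj)
            s_sums[it] += s_val
            lcc_sums[it] += frac
            prev_m = mm
            prev_s = s_val
            prev_lcc = frac
    return s_sums, lcc_sums
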