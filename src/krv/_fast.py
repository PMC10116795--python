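"""Numba inner loops for the abundance-weighted UniFrac family and for
Monte-Carlo permutation of the KRV trace statistic."""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def weighted_unifrac_pairs(P, lengths):
    """Normalized weighted UniFrac: sum_b l_b |p_ib - p_jb| / sum_b l_b (p_ib + p_jb).

    P is the (n, B) branch-proportion matrix, lengths the (B,) branch lengths.
    """
    n, B = P.shape
    D = np.zeros((n, n))
    s = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for b in range(B):
            acc += lengths[b] * P[i, b]
        s[i] = acc
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            for b in range(B):
                d = P[i, b] - P[j, b]
                num += lengths[b] * abs(d)
            den = s[i] + s[j]
            val = num / den if den > 0 else 0.0
            D[i, j] = val
            D[j, i] = val
    return D


@njit(cache=True, fastmath=True)
def generalized_unifrac_pairs(P, lengths, alpha):
    """Generalized UniFrac with exponent alpha on the branch total proportion."""
    n, B = P.shape
    D = np.zeros((n, n))
    half = alpha == 0.5
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            den = 0.0
            for b in range(B):
                pi = P[i, b]
                pj = P[j, b]
                s = pi + pj
                if s <= 0.0:
                    continue
                if half:
                    w = lengths[b] * np.sqrt(s)
                else:
                    w = lengths[b] * s ** alpha
                num += w * abs(pi - pj) / s
                den += w
            val = num / den if den > 0 else 0.0
            D[i, j] = val
            D[j, i] = val
    return D


@njit(cache=True, fastmath=True)
def weighted_and_generalized_pairs(P, lengths, alpha):
    """Weighted-normalized and generalized UniFrac in a single pass over the
    branch axis (they share the per-pair |p_ib - p_jb| scan)."""
    n, B = P.shape
    Dw = np.zeros((n, n))
    Dg = np.zeros((n, n))
    s = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for b in range(B):
            acc += lengths[b] * P[i, b]
        s[i] = acc
    half = alpha == 0.5
    for i in range(n):
        for j in range(i + 1, n):
            wnum = 0.0
            gnum = 0.0
            gden = 0.0
            for b in range(B):
                pi = P[i, b]
                pj = P[j, b]
                tot = pi + pj
                if tot <= 0.0:
                    continue
                d = abs(pi - pj)
                wnum += lengths[b] * d
                if half:
                    w = lengths[b] * np.sqrt(tot)
                else:
                    w = lengths[b] * tot ** alpha
                gnum += w * d / tot
                gden += w
            den = s[i] + s[j]
            vw = wnum / den if den > 0 else 0.0
            vg = gnum / gden if gden > 0 else 0.0
            Dw[i, j] = vw
            Dw[j, i] = vw
            Dg[i, j] = vg
            Dg[j, i] = vg
    return Dw, Dg


@njit(cache=True)
def permuted_trace_stats(W1, W2, perms):
    """tr(W1 P W2 P') for each permutation row in perms (B, n)."""
    B, n = perms.shape
    out = np.empty(B)
    for b in range(B):
        p = perms[b]
        acc = 0.0
        for i in range(n):
            pi = p[i]
            for j in range(n):
                acc += W1[i, j] * W2[pi, p[j]]
        out[b] = acc
    return out
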