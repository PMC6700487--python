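"""Numba inner loops for folding and local alignment.

All kernels are O(n^2)-O(n^3) dynamic programs over dense float/int
arrays; keeping them here isolates the jit layer from the public API.
Sequences arrive pre-encoded as small integer arrays (A=0, C=1, G=2,
U=3, N=4); ``etab``/``wtab`` are 5x5 lookup tables where entry 0 means
"not pairable".
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mfe_fill(enc, etab, min_loop):
    """Max-weight (Nussinov-style) fill; W[i, j] is the best score on [i, j]."""
    n = enc.shape[0]
    W = np.zeros((n, n), dtype=np.float64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                e = etab[enc[i], enc[k]]
                if e > 0.0:
                    v = e + W[i + 1, k - 1]
                    if k + 1 <= j:
                        v += W[k + 1, j]
                    if v > best:
                        best = v
            W[i, j] = best
    return W


@njit(cache=True)
def inside_fill(enc, wtab, min_loop, s0):
    """Scaled McCaskill inside pass over half-open regions.

    Z[i, j] is the scaled partition function of region [i, j); every
    nucleotide carries a factor s0 (folded into wtab for paired bases),
    so a full structure's weight is exp(-E/RT) * s0^n independent of
    how the bases are partitioned.
    """
    n = enc.shape[0]
    Z = np.zeros((n + 1, n + 1), dtype=np.float64)
    for i in range(n + 1):
        Z[i, i] = 1.0
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n + 1):
            acc = s0 * Z[i + 1, j]
            for k in range(i + min_loop + 1, j):
                w = wtab[enc[i], enc[k]]
                if w > 0.0:
                    acc += w * Z[i + 1, k] * Z[k + 1, j]
            Z[i, j] = acc
    return Z


@njit(cache=True)
def outside_fill(enc, wtab, min_loop, s0, Z):
    """Outside pass matching :func:`inside_fill`'s decomposition.

    O[i, j] sums the weights of all contexts of region [i, j): the three
    terms mirror where Z[i, j] occurs in the inside recursion (leftmost
    base of the enclosing region unpaired; [i, j) as the interior of an
    enclosing pair (i-1, j); [i, j) as the right sibling of a pair
    (a, i-1)).
    """
    n = enc.shape[0]
    O = np.zeros((n + 1, n + 1), dtype=np.float64)
    O[0, n] = 1.0
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            acc = s0 * O[i - 1, j]
            if j <= n - 1 and j - (i - 1) > min_loop:
                w = wtab[enc[i - 1], enc[j]]
                if w > 0.0:
                    s = 0.0
                    for b in range(j + 1, n + 1):
                        s += Z[j + 1, b] * O[i - 1, b]
                    acc += w * s
            for a in range(0, i - 1 - min_loop):
                w = wtab[enc[a], enc[i - 1]]
                if w > 0.0:
                    acc += w * Z[a + 1, i - 1] * O[a, j]
            O[i, j] = acc
    return O


@njit(cache=True)
def pair_probs(enc, wtab, min_loop, Z, O):
    """Base-pair probability matrix from the inside/outside tables."""
    n = enc.shape[0]
    P = np.zeros((n, n), dtype=np.float64)
    total = Z[0, n]
    for p in range(n):
        for q in range(p + min_loop + 1, n):
            w = wtab[enc[p], enc[q]]
            if w > 0.0:
                s = 0.0
                for b in range(q + 1, n + 1):
                    s += Z[q + 1, b] * O[p, b]
                val = w * Z[p + 1, q] * s / total
                P[p, q] = val
                P[q, p] = val
    return P


@njit(cache=True)
def sw_fill(q, r, match, mismatch, gap):
    """Smith-Waterman score matrix with linear gaps.

    Returns (H, best score, best i, best j); ties on the best cell keep
    the first occurrence in row-major order.
    """
    nq = q.shape[0]
    nr = r.shape[0]
    H = np.zeros((nq + 1, nr + 1), dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            vu = H[i - 1, j] + gap
            vl = H[i, j - 1] + gap
            h = v
            if vu > h:
                h = vu
            if vl > h:
                h = vl
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, best, bi, bj
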