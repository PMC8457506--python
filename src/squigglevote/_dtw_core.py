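"""Numba kernels for the DTW dynamic programme.

Local cost is the scalar Euclidean distance |a_i - b_j| with unit step
weights over the step set {(1,0), (0,1), (1,1)}.  Traceback tie-breaking
prefers the diagonal, then the move consuming side A; this is deterministic
so every caller sees the same optimal path.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def accumulated_cost(a, b):
    n = a.shape[0]
    m = b.shape[0]
    D = np.empty((n, m), dtype=np.float64)
    D[0, 0] = abs(a[0] - b[0])
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = abs(a[i] - b[j]) + best
    return D


@njit(cache=True)
def traceback(D):
    n, m = D.shape
    max_len = n + m - 1
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i = n - 1
    j = m - 1
    t = max_len - 1
    pi[t] = i
    pj[t] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        t -= 1
        pi[t] = i
        pj[t] = j
    return pi[t:], pj[t:]


@njit(cache=True)
def distance_only(a, b):
    """Two-row DP: DTW distance without materialising the full matrix."""
    n = a.shape[0]
    m = b.shape[0]
    prev = np.empty(m, dtype=np.float64)
    cur = np.empty(m, dtype=np.float64)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(a[i] - b[j]) + best
        prev, cur = cur, prev
    return prev[m - 1]
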